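"""Sigma-profile data model, descriptor naming and table assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ilqsar.descriptors import (
    N_GRID,
    SIGMA_GRID,
    DescriptorTable,
    SigmaProfile,
    all_bin_names,
    assemble_pair_descriptors,
    bin_label,
    correlation_matrix,
    parse_bin,
    read_ion_profiles,
    write_ion_profiles,
)


def delta_profile(ion_id, species, sigma, mass=1.0):
    values = np.zeros(N_GRID)
    values[np.argmin(np.abs(SIGMA_GRID - sigma))] = mass
    return SigmaProfile(ion_id, species, values)


class TestBinLabel:
    @pytest.mark.parametrize("species,sigma,expected", [
        ("cation", -0.008, "C-0.008"),
        ("anion", 0.004, "A0.004"),
        ("cation", 0.0, "C0.000"),
        ("anion", -0.030, "A-0.030"),
        ("cation", 0.030, "C0.030"),
    ])
    def test_formatting(self, species, sigma, expected):
        assert bin_label(species, sigma) == expected

    @pytest.mark.parametrize("sigma", [0.0005, 0.031, -0.0305, 1.0])
    def test_off_grid_sigma_rejected(self, sigma):
        with pytest.raises(ValueError, match=str(sigma)):
            bin_label("cation", sigma)

    def test_all_122_names_round_trip(self):
        names = all_bin_names()
        assert len(names) == 2 * N_GRID == 122
        for name in names:
            species, sigma = parse_bin(name)
            assert bin_label(species, sigma) == name

    @given(st.integers(-30, 30), st.sampled_from(["cation", "anion"]))
    @settings(derandomize=True, max_examples=60)
    def test_label_parse_is_lossless(self, step, species):
        sigma = step / 1000.0
        sp, s = parse_bin(bin_label(species, sigma))
        assert sp == species and abs(s - sigma) < 1e-12


class TestSigmaProfile:
    def test_grid_is_61_points_with_fixed_spacing(self):
        assert len(SIGMA_GRID) == 61
        assert np.allclose(np.diff(SIGMA_GRID), 0.001, atol=1e-12)
        assert SIGMA_GRID[0] == -0.030 and SIGMA_GRID[-1] == 0.030

    def test_negative_values_rejected(self):
        values = np.zeros(N_GRID)
        values[5] = -1.0
        with pytest.raises(ValueError, match="ion1"):
            SigmaProfile("ion1", "cation", values)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="60"):
            SigmaProfile("ion1", "anion", np.zeros(60))

    def test_empty_id_rejected(self):
        with pytest.raises(ValueError):
            SigmaProfile("", "cation", np.zeros(N_GRID))


class TestIonProfileIO:
    def _profiles(self):
        rng = np.random.default_rng(1)
        return {
            "cat1": SigmaProfile("cat1", "cation", rng.uniform(0, 30, N_GRID)),
            "an1": SigmaProfile("an1", "anion", rng.uniform(0, 30, N_GRID)),
        }

    def test_round_trip_preserves_values(self, tmp_path):
        path = tmp_path / "ions.csv"
        profiles = self._profiles()
        write_ion_profiles(profiles, path)
        back = read_ion_profiles(path)
        assert set(back) == set(profiles)
        for ion_id in profiles:
            np.testing.assert_allclose(back[ion_id].values,
                                       profiles[ion_id].values, rtol=1e-12)
            assert back[ion_id].species == profiles[ion_id].species

    def test_missing_sigma_column_reported(self, tmp_path):
        path = tmp_path / "ions.csv"
        write_ion_profiles(self._profiles(), path)
        df = pd.read_csv(path).drop(columns=["s0.004"])
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="s0.004"):
            read_ion_profiles(path)

    def test_negative_value_names_ion(self, tmp_path):
        path = tmp_path / "ions.csv"
        profiles = self._profiles()
        write_ion_profiles(profiles, path)
        df = pd.read_csv(path)
        df.loc[0, "s0.000"] = -1.0
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="negative"):
            read_ion_profiles(path)

    def test_duplicate_ion_id_rejected(self, tmp_path):
        path = tmp_path / "ions.csv"
        profiles = self._profiles()
        write_ion_profiles(profiles, path)
        df = pd.read_csv(path)
        df.loc[1, "ion_id"] = df.loc[0, "ion_id"]
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_ion_profiles(path)


class TestAssemblePair:
    def test_anion_with_no_mass_in_requested_bins_gives_zeros(self):
        # a chloride-like anion: all surface area below sigma = -0.006
        values = np.zeros(N_GRID)
        values[SIGMA_GRID < -0.006] = 5.0
        anion = SigmaProfile("chloride", "anion", values)
        cation = delta_profile("cat", "cation", 0.002, mass=7.5)
        vec = assemble_pair_descriptors(cation, anion,
                                        ["A-0.006", "A-0.001", "A0.004"])
        assert list(vec.entries.values()) == [0.0, 0.0, 0.0]

    def test_delta_cation_hits_single_bin(self):
        cation = delta_profile("cat", "cation", 0.002, mass=3.25)
        anion = delta_profile("an", "anion", -0.004)
        bins = ["C-0.004", "C0.002", "C0.010"]
        vec = assemble_pair_descriptors(cation, anion, bins)
        assert vec.entries == {"C-0.004": 0.0, "C0.002": 3.25, "C0.010": 0.0}

    def test_bin_order_is_permutation_equivariant(self):
        rng = np.random.default_rng(3)
        cation = SigmaProfile("c", "cation", rng.uniform(0, 10, N_GRID))
        anion = SigmaProfile("a", "anion", rng.uniform(0, 10, N_GRID))
        bins = ["C-0.008", "A0.004", "C0.002"]
        fwd = assemble_pair_descriptors(cation, anion, bins)
        rev = assemble_pair_descriptors(cation, anion, bins[::-1])
        assert fwd.names == bins and rev.names == bins[::-1]
        for b in bins:
            assert fwd.entries[b] == rev.entries[b]

    def test_species_mismatch_rejected(self):
        cation = delta_profile("c", "cation", 0.0)
        anion = delta_profile("a", "anion", 0.0)
        with pytest.raises(ValueError):
            assemble_pair_descriptors(anion, cation, ["C0.000"])

    def test_linearity_in_each_profile(self):
        rng = np.random.default_rng(4)
        cation = SigmaProfile("c", "cation", rng.uniform(0, 10, N_GRID))
        anion = SigmaProfile("a", "anion", rng.uniform(0, 10, N_GRID))
        scaled = SigmaProfile("c2", "cation", 3.0 * cation.values)
        bins = ["C-0.010", "C0.000", "C0.010", "A0.000"]
        base = assemble_pair_descriptors(cation, anion, bins)
        big = assemble_pair_descriptors(scaled, anion, bins)
        for b in bins:
            factor = 3.0 if b.startswith("C") else 1.0
            assert big.entries[b] == pytest.approx(factor * base.entries[b])


class TestCorrelationMatrix:
    def _table(self):
        data = pd.DataFrame({
            "C0.000": [1.0, 2.0, 3.0],
            "C0.001": [2.0, 4.0, 6.5],
            "C0.002": [1.0, 2.0, 3.0],  # duplicate of C0.000
        }, index=["a", "b", "c"])
        return DescriptorTable(data=data)

    def test_diagonal_is_one_and_matrix_symmetric(self):
        r = correlation_matrix(self._table())
        np.testing.assert_allclose(np.diag(r), 1.0)
        np.testing.assert_allclose(r.to_numpy(), r.to_numpy().T)
        assert (r.to_numpy() <= 1.0).all() and (r.to_numpy() >= -1.0).all()

    def test_duplicated_column_correlates_exactly(self):
        r = correlation_matrix(self._table())
        assert r.loc["C0.000", "C0.002"] == pytest.approx(1.0)

    def test_matches_direct_pearson_formula(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 6.5])
        expected = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        r = correlation_matrix(self._table())
        assert r.loc["C0.000", "C0.001"] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_column_named_in_error(self):
        data = pd.DataFrame({"C0.000": [1.0, 1.0, 1.0], "C0.001": [1, 2, 3]},
                            index=list("abc"))
        with pytest.raises(ValueError, match="C0.000"):
            correlation_matrix(DescriptorTable(data=data))
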