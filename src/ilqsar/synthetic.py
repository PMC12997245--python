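"""Synthetic sigma-profile studies with a planted linear response.

Real descriptor tables come from quantum-chemical COSMO-RS calculations;
this module emulates their structure so that every pipeline stage (assembly,
fitting, selection, validation, applicability domain) can be exercised and
checked against known ground truth.  Ion profiles are mixtures of Gaussian
bumps over the sigma grid — smooth, non-negative, with neighbouring bins
correlated the way real profiles are — and the toxicity response is a known
linear model over a small set of planted bins plus Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import (
    N_GRID,
    SIGMA_GRID,
    DescriptorTable,
    SigmaProfile,
    all_bin_names,
    build_descriptor_table,
    ILRecord,
)
from .mlr import MLRModel, published_model


def default_planted_model() -> MLRModel:
    """Planted truth mirroring the published model's shape: 8 cationic and
    3 anionic bins, anion coefficients several-fold smaller than cationic.

    Coefficients are the published ones scaled to a tenth so that, on the
    generator's profile scale, the response spread stays on the ~1 log uM
    scale of measured Log 1/EC50 values."""
    m = published_model()
    coefs = {k: 0.1 * v for k, v in m.coefficients.items()}
    return MLRModel(m.descriptor_names, coefs, m.intercept,
                    meta={"source": "synthetic planted truth"})


@dataclass
class SyntheticSpec:
    """Study-scale defaults follow the modelled dataset: 113 cations and
    29 anions combining into 243 ionic liquids, split 75:25 into training
    and test.  When ``noise_sd`` is None it is calibrated so the planted
    signal explains ``target_r2`` of the response variance."""

    n_cations: int = 113
    n_anions: int = 29
    n_ils: int = 243
    bump_width: float = 0.004  # e/A^2; couples adjacent bins
    total_area_range: tuple[float, float] = (100.0, 500.0)
    planted_model: MLRModel = field(default_factory=default_planted_model)
    noise_sd: float | None = None  # log uM; None -> calibrate to target_r2
    target_r2: float = 0.82
    split_frac: float = 0.75
    n_outliers: int = 0
    outlier_scale: float = 6.0  # in units of noise_sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ils > self.n_cations * self.n_anions:
            raise ValueError("n_ils exceeds the number of distinct pairs")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 < self.split_frac < 1.0):
            raise ValueError("split_frac must be in (0, 1)")


def _gen_profile(rng: np.random.Generator, ion_id: str, species: str,
                 spec: SyntheticSpec) -> SigmaProfile:
    n_bumps = int(rng.integers(1, 4))
    # species bias: cation bumps sit at positive sigma on average, anions negative
    lo, hi = (-0.010, 0.020) if species == "cation" else (-0.020, 0.010)
    centers = rng.uniform(lo, hi, size=n_bumps)
    widths = spec.bump_width * rng.uniform(0.6, 1.6, size=n_bumps)
    weights = rng.dirichlet(np.ones(n_bumps))
    total = rng.uniform(*spec.total_area_range)
    values = np.zeros(N_GRID)
    for c, w, wt in zip(centers, widths, weights):
        shape = np.exp(-0.5 * ((SIGMA_GRID - c) / w) ** 2)
        values += total * wt * shape / shape.sum()
    return SigmaProfile(ion_id=ion_id, species=species, values=values)


def gen_ion_profiles(spec: SyntheticSpec,
                     rng: np.random.Generator | None = None) -> dict[str, SigmaProfile]:
    """Generate the cation and anion sigma-profile library for a study."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    profiles: dict[str, SigmaProfile] = {}
    for i in range(spec.n_cations):
        ion_id = f"CAT{i + 1}"
        profiles[ion_id] = _gen_profile(rng, ion_id, "cation", spec)
    for i in range(spec.n_anions):
        ion_id = f"ANI{i + 1}"
        profiles[ion_id] = _gen_profile(rng, ion_id, "anion", spec)
    return profiles


def gen_dataset(spec: SyntheticSpec, return_details: bool = False):
    """Generate a full synthetic study: descriptor table, planted response
    with Gaussian noise, and a train/test split.

    Returns the DescriptorTable (all 122 bins, response, set labels);
    with ``return_details=True`` also a dict holding the profiles, records,
    noise-free response and the realized noise standard deviation.
    """
    rng = np.random.default_rng(spec.seed)
    profiles = gen_ion_profiles(spec, rng)

    n_pairs = spec.n_cations * spec.n_anions
    chosen = rng.choice(n_pairs, size=spec.n_ils, replace=False)
    records = []
    for idx, flat in enumerate(np.sort(chosen)):
        ci, ai = divmod(int(flat), spec.n_anions)
        records.append(ILRecord(
            il_id=f"IL{idx + 1}", name=f"CAT{ci + 1} ANI{ai + 1}",
            cation_id=f"CAT{ci + 1}", anion_id=f"ANI{ai + 1}"))
    table = build_descriptor_table(records, profiles, bins=all_bin_names())

    planted = spec.planted_model
    dead = [n for n in planted.descriptor_names
            if (table.data[n] == 0).all()]
    if dead:
        raise ValueError(f"planted bin(s) zero across all ILs: {dead}")
    signal = (table.data[planted.descriptor_names].to_numpy()
              @ planted.coef_vector() + planted.intercept)

    if spec.noise_sd is None:
        var_sig = float(np.var(signal))
        noise_sd = float(np.sqrt(var_sig * (1.0 - spec.target_r2) / spec.target_r2))
    else:
        noise_sd = spec.noise_sd
    y = signal + rng.normal(0.0, noise_sd, size=spec.n_ils) if noise_sd > 0 \
        else signal.copy()

    outlier_ids: list[str] = []
    if spec.n_outliers:
        rows = rng.choice(spec.n_ils, size=spec.n_outliers, replace=False)
        signs = rng.choice([-1.0, 1.0], size=spec.n_outliers)
        scale = spec.outlier_scale * (noise_sd if noise_sd > 0 else 1.0)
        y[rows] += signs * scale
        outlier_ids = [table.il_ids[r] for r in rows]

    n_test = int(np.floor((1.0 - spec.split_frac) * spec.n_ils))
    test_rows = rng.choice(spec.n_ils, size=n_test, replace=False)
    labels = np.array(["train"] * spec.n_ils, dtype=object)
    labels[test_rows] = "test"

    ids = table.il_ids
    out = DescriptorTable(
        data=table.data,
        response=pd.Series(y, index=ids, name="log_inv_ec50"),
        set_label=pd.Series(labels, index=ids, name="set"),
    )
    if not return_details:
        return out
    return out, {
        "profiles": profiles,
        "records": records,
        "signal": pd.Series(signal, index=ids),
        "noise_sd": noise_sd,
        "outlier_ids": outlier_ids,
    }
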