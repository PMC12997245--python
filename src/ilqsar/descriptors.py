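"""Sigma-profile descriptors for ionic-liquid QSAR modelling.

A COSMO-RS sigma profile summarises a molecular surface as the amount of
surface area found at each screening-charge density sigma (e/A^2).  Profiles
are tabulated on a fixed grid of 61 points from -0.030 to +0.030 at 0.001
steps.  An ionic liquid is a cation/anion pair, so its descriptor vector
concatenates values read off the cation profile (bins named ``C<sigma>``)
and the anion profile (bins named ``A<sigma>``), e.g. ``C-0.008`` or
``A0.004``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SIGMA_STEP = 0.001
N_GRID = 61
#: The fixed surface-charge-density grid, -0.030 ... +0.030 e/A^2 inclusive.
SIGMA_GRID = np.round(np.arange(-30, 31) * SIGMA_STEP, 3)

_SPECIES_PREFIX = {"cation": "C", "anion": "A"}
_PREFIX_SPECIES = {"C": "cation", "A": "anion"}
_NAME_RE = re.compile(r"^([CA])(-?\d\.\d{3})$")


def _format_sigma(sigma: float) -> str:
    # 3 decimals, "-" for negatives, no "+"; -0.0 collapses to 0.000
    return f"{sigma + 0.0:.3f}"


def grid_index(sigma: float) -> int:
    """Index of *sigma* on the fixed grid; raises if off-grid."""
    idx = (sigma - SIGMA_GRID[0]) / SIGMA_STEP
    nearest = int(round(idx))
    if not (0 <= nearest < N_GRID) or abs(idx - nearest) > 1e-6:
        raise ValueError(
            f"sigma={sigma!r} is not on the descriptor grid "
            f"[-0.030, 0.030] step 0.001"
        )
    return nearest


def bin_label(species: str, sigma: float) -> str:
    """Descriptor name for a species/sigma pair, e.g. ``("cation", -0.008)``
    -> ``"C-0.008"``."""
    if species not in _SPECIES_PREFIX:
        raise ValueError(f"unknown species {species!r}; expected cation or anion")
    return _SPECIES_PREFIX[species] + _format_sigma(SIGMA_GRID[grid_index(sigma)])


def parse_bin(name: str) -> tuple[str, float]:
    """Inverse of :func:`bin_label`: ``"A0.004"`` -> ``("anion", 0.004)``."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"malformed descriptor name {name!r}")
    species = _PREFIX_SPECIES[m.group(1)]
    sigma = float(m.group(2))
    grid_index(sigma)  # range check
    return species, sigma


def all_bin_names() -> list[str]:
    """All 122 candidate descriptor names: 61 cationic then 61 anionic."""
    return [bin_label("cation", s) for s in SIGMA_GRID] + [
        bin_label("anion", s) for s in SIGMA_GRID
    ]


@dataclass
class SigmaProfile:
    """One ion's surface-area distribution over the sigma grid."""

    ion_id: str
    species: str  # "cation" | "anion"
    values: np.ndarray  # 61 non-negative surface amounts (A^2)

    def __post_init__(self) -> None:
        if not self.ion_id:
            raise ValueError("ion_id must be non-empty")
        if self.species not in _SPECIES_PREFIX:
            raise ValueError(f"unknown species {self.species!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_GRID,):
            raise ValueError(
                f"profile for {self.ion_id!r} has {self.values.size} values, "
                f"expected {N_GRID}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"profile for {self.ion_id!r} has non-finite values")
        if np.any(self.values < 0):
            raise ValueError(f"profile for {self.ion_id!r} has negative values")

    def value_at(self, sigma: float) -> float:
        return float(self.values[grid_index(sigma)])

    def centroid(self) -> float:
        """Area-weighted mean sigma; sign indicates the dominant polarity."""
        total = self.values.sum()
        if total == 0:
            return 0.0
        return float((SIGMA_GRID * self.values).sum() / total)


@dataclass
class DescriptorVector:
    """Named descriptor values for one ionic liquid (cation bins first)."""

    il_id: str
    entries: dict[str, float]

    def __post_init__(self) -> None:
        for name in self.entries:
            parse_bin(name)

    @property
    def names(self) -> list[str]:
        return list(self.entries)

    def as_series(self) -> pd.Series:
        return pd.Series(self.entries, name=self.il_id, dtype=float)


@dataclass
class ILRecord:
    """One dataset row: an ionic liquid and its measured toxicity."""

    il_id: str
    name: str
    cation_id: str
    anion_id: str
    log_inv_ec50: float | None = None


@dataclass
class DescriptorTable:
    """IL-by-descriptor matrix with optional response and train/test labels.

    ``data`` is indexed by il_id with one column per descriptor name;
    ``response`` holds Log 1/EC50 (log uM) and ``set_label`` holds
    "train"/"test" membership for the rows that have one.
    """

    data: pd.DataFrame
    response: pd.Series | None = None
    set_label: pd.Series | None = None

    def __post_init__(self) -> None:
        for name in self.data.columns:
            parse_bin(name)
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate il_id(s): {dupes}")
        if self.response is not None:
            self.response = self.response.astype(float)
            extra = self.response.index.difference(self.data.index)
            if len(extra):
                raise ValueError(f"response ids not in table: {extra.tolist()}")
        if self.set_label is not None:
            bad = set(self.set_label.dropna()) - {"train", "test"}
            if bad:
                raise ValueError(f"invalid set labels: {sorted(bad)}")

    @property
    def il_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def descriptor_names(self) -> list[str]:
        return self.data.columns.tolist()

    def subset(self, labels: str | list[str]) -> "DescriptorTable":
        """Rows carrying the given set label(s)."""
        if self.set_label is None:
            raise ValueError("table has no train/test labels")
        if isinstance(labels, str):
            labels = [labels]
        ids = self.set_label[self.set_label.isin(labels)].index
        return DescriptorTable(
            data=self.data.loc[ids],
            response=None if self.response is None else self.response.loc[ids],
            set_label=self.set_label.loc[ids],
        )

    def matrix(self, names: list[str] | None = None) -> np.ndarray:
        names = self.descriptor_names if names is None else list(names)
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise KeyError(f"descriptors not in table: {missing}")
        return self.data[names].to_numpy(dtype=float)


def assemble_pair_descriptors(
    cation: SigmaProfile, anion: SigmaProfile, bins: list[str], il_id: str = ""
) -> DescriptorVector:
    """Read the requested bins off a cation/anion profile pair.

    Cationic bins (``C...``) are taken from *cation*, anionic bins from
    *anion*; the output order follows *bins*.
    """
    if cation.species != "cation":
        raise ValueError(f"{cation.ion_id!r} is not a cation")
    if anion.species != "anion":
        raise ValueError(f"{anion.ion_id!r} is not an anion")
    entries: dict[str, float] = {}
    for b in bins:
        if b in entries:
            raise ValueError(f"duplicate bin {b!r}")
        species, sigma = parse_bin(b)
        ion = cation if species == "cation" else anion
        entries[b] = ion.value_at(sigma)
    return DescriptorVector(il_id=il_id or f"{cation.ion_id}.{anion.ion_id}", entries=entries)


def build_descriptor_table(
    records: list[ILRecord],
    profiles: dict[str, SigmaProfile],
    bins: list[str] | None = None,
    set_labels: dict[str, str] | None = None,
) -> DescriptorTable:
    """Assemble the full IL-by-descriptor table for a list of dataset rows."""
    bins = all_bin_names() if bins is None else list(bins)
    rows, resp = {}, {}
    for rec in records:
        cat = profiles.get(rec.cation_id)
        ani = profiles.get(rec.anion_id)
        if cat is None or ani is None:
            missing = rec.cation_id if cat is None else rec.anion_id
            raise KeyError(f"no profile for ion {missing!r} (IL {rec.il_id!r})")
        vec = assemble_pair_descriptors(cat, ani, bins, il_id=rec.il_id)
        rows[rec.il_id] = vec.entries
        if rec.log_inv_ec50 is not None:
            resp[rec.il_id] = rec.log_inv_ec50
    data = pd.DataFrame.from_dict(rows, orient="index")[bins]
    response = pd.Series(resp, dtype=float) if resp else None
    labels = None
    if set_labels:
        labels = pd.Series(set_labels).reindex(data.index).dropna()
    return DescriptorTable(data=data, response=response, set_label=labels)


def drop_all_zero_bins(table: DescriptorTable) -> DescriptorTable:
    """Remove descriptor columns that are zero for every IL (unidentifiable)."""
    keep = table.data.columns[(table.data != 0).any(axis=0)]
    return DescriptorTable(
        data=table.data[keep], response=table.response, set_label=table.set_label
    )


# ---------------------------------------------------------------------------
# file I/O

def _sigma_columns() -> list[str]:
    return [f"s{_format_sigma(s)}" for s in SIGMA_GRID]


def read_ion_profiles(path) -> dict[str, SigmaProfile]:
    """Read ion sigma-profiles from a CSV with columns
    ``ion_id,species,s-0.030,...,s0.030``."""
    df = pd.read_csv(path, dtype={"ion_id": str, "species": str})
    expected = _sigma_columns()
    missing = [c for c in ["ion_id", "species"] + expected if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in {"ion_id", "species", *expected}]
    if extra:
        raise ValueError(f"{path}: unexpected column(s) {extra}")
    profiles: dict[str, SigmaProfile] = {}
    for i, row in df.iterrows():
        ion_id = row["ion_id"]
        if ion_id in profiles:
            raise ValueError(f"{path} row {i + 2}: duplicate ion_id {ion_id!r}")
        try:
            profiles[ion_id] = SigmaProfile(
                ion_id=ion_id,
                species=row["species"],
                values=row[expected].to_numpy(dtype=float),
            )
        except ValueError as exc:
            raise ValueError(f"{path} row {i + 2}: {exc}") from exc
    return profiles


def write_ion_profiles(profiles: dict[str, SigmaProfile], path) -> None:
    cols = _sigma_columns()
    recs = [
        {"ion_id": p.ion_id, "species": p.species, **dict(zip(cols, p.values))}
        for p in profiles.values()
    ]
    pd.DataFrame(recs).to_csv(path, index=False, float_format="%.17g")


def read_dataset(path) -> list[ILRecord]:
    """Read IL records from ``il_id,name,cation_id,anion_id,log_inv_ec50,set``."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["il_id", "name", "cation_id", "anion_id", "log_inv_ec50"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    records, labels = [], {}
    for _, row in df.iterrows():
        y = float(row["log_inv_ec50"]) if row["log_inv_ec50"] != "" else None
        records.append(
            ILRecord(row["il_id"], row["name"], row["cation_id"], row["anion_id"], y)
        )
        if "set" in df.columns and row["set"] in ("train", "test"):
            labels[row["il_id"]] = row["set"]
    return records, labels


def read_descriptor_file(path) -> DescriptorTable:
    """Read a pre-assembled descriptor table: ``il_id,<bins...>[,log_inv_ec50][,set]``."""
    df = pd.read_csv(path).set_index("il_id")
    response = None
    if "log_inv_ec50" in df.columns:
        response = df.pop("log_inv_ec50").dropna()
    labels = None
    if "set" in df.columns:
        labels = df.pop("set").dropna()
    return DescriptorTable(data=df.astype(float), response=response, set_label=labels)


def write_descriptor_file(table: DescriptorTable, path) -> None:
    df = table.data.copy()
    if table.response is not None:
        df["log_inv_ec50"] = table.response
    if table.set_label is not None:
        df["set"] = table.set_label
    df.to_csv(path, index_label="il_id", float_format="%.17g")


def correlation_matrix(table: DescriptorTable, names: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlation of descriptor columns.

    Raises if any requested column has zero variance (correlation undefined)
    or the table has fewer than 3 rows.
    """
    names = table.descriptor_names if names is None else list(names)
    X = table.matrix(names)
    if X.shape[0] < 3:
        raise ValueError("correlation needs at least 3 rows")
    sd = X.std(axis=0)
    dead = [n for n, s in zip(names, sd) if s == 0]
    if dead:
        raise ValueError(f"zero-variance descriptor column(s): {dead}")
    r = np.corrcoef(X, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=names, columns=names)
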