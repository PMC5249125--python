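"""Pairwise p-distances with pairwise deletion, and barcoding-gap summaries.

The p-distance between two aligned sequences is the fraction of differing
sites among the sites where both sequences carry an unambiguous A/C/G/T
(pairwise deletion: gaps, Ns and ambiguity codes are missing data for that
pair only).  Per-species summaries give mean/maximum intraspecific distance
and the distance to the nearest heterospecific neighbour; a species has a
"barcode gap" when its maximum intraspecific distance is smaller than its
nearest-neighbour distance.

p-distance with pairwise deletion is not a metric (the triangle inequality
can fail when different site subsets are compared per pair); nothing here
relies on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io import BarcodeLibrary

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode_alignment(sequences: list[str]) -> np.ndarray:
    """Encode sequences as an (n, L) int8 array; non-ACGT symbols become -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        lut[ord(base)] = code
    arr = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    return lut[arr].reshape(len(sequences), -1)


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with per-pair comparable-site counts.

    Entries whose pair shares zero comparable sites are NaN in ``d`` and 0 in
    ``sites``; they are excluded from every downstream summary.
    """

    ids: list[str]
    d: np.ndarray
    sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        assert self.d.shape == (n, n) and self.sites.shape == (n, n)

    def index(self, specimen_id: str) -> int:
        return self.ids.index(specimen_id)

    def submatrix(self, keep_ids: list[str]) -> "DistanceMatrix":
        idx = [self.index(i) for i in keep_ids]
        return DistanceMatrix(
            list(keep_ids), self.d[np.ix_(idx, idx)], self.sites[np.ix_(idx, idx)]
        )

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                rows.append(
                    (self.ids[i], self.ids[j], self.d[i, j], int(self.sites[i, j]))
                )
        return pd.DataFrame(rows, columns=["id_a", "id_b", "distance", "sites"])

    def to_phylip(self, path) -> None:
        """Square PHYLIP distance matrix (undefined pairs written as -1)."""
        d = np.where(np.isnan(self.d), -1.0, self.d)
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, sid in enumerate(self.ids):
                row = " ".join(f"{x:.6f}" for x in d[i])
                fh.write(f"{sid[:10]:<10} {row}\n")


def p_distance(a: str, b: str) -> tuple[float, int]:
    """p-distance and comparable-site count for one sequence pair.

    Returns (nan, 0) when no site is comparable.
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal aligned lengths")
    enc = encode_alignment([a.upper(), b.upper()])
    both = (enc[0] >= 0) & (enc[1] >= 0)
    n_comp = int(both.sum())
    if n_comp == 0:
        return float("nan"), 0
    mism = int(((enc[0] != enc[1]) & both).sum())
    return mism / n_comp, n_comp


def distance_matrix(library: BarcodeLibrary) -> DistanceMatrix:
    """All-pairs p-distance matrix (pairwise deletion) for a validated library."""
    ids = library.ids()
    enc = encode_alignment([r.sequence for r in library])
    n = len(ids)
    valid = enc >= 0
    d = np.zeros((n, n), dtype=float)
    sites = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(sites, valid.sum(axis=1))
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        comp = both.sum(axis=1)
        mism = ((enc[i] != enc[i + 1 :]) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(comp > 0, mism / np.maximum(comp, 1), np.nan)
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
        sites[i, i + 1 :] = comp
        sites[i + 1 :, i] = comp
    return DistanceMatrix(ids, d, sites)


@dataclass
class SpeciesDistanceSummary:
    """One barcoding-gap table row (distances as fractions)."""

    species: str
    n: int
    mean_intra: Optional[float]
    max_intra: Optional[float]
    nn_species: Optional[str]
    nn_distance: Optional[float]
    gap_present: Optional[bool]
    n_undefined_pairs: int = 0


def species_summaries(
    m: DistanceMatrix,
    labels: dict[str, str],
    nn_semantics: str = "min",
) -> list[SpeciesDistanceSummary]:
    """Per-species distance summaries.

    ``nn_semantics`` selects how the nearest-neighbour distance is scored:
    "min" (default) takes the smallest heterospecific specimen-pair distance;
    "mean" averages all specimen pairs against each candidate species and
    takes the closest species by that mean.
    """
    if nn_semantics not in ("min", "mean"):
        raise ValueError("nn_semantics must be 'min' or 'mean'")
    missing = [i for i in m.ids if i not in labels]
    if missing:
        raise ValueError(f"specimens without species label: {missing[:5]}")
    species = sorted({labels[i] for i in m.ids})
    idx_by_sp = {
        sp: np.array([k for k, i in enumerate(m.ids) if labels[i] == sp])
        for sp in species
    }
    out = []
    for sp in species:
        own = idx_by_sp[sp]
        intra = m.d[np.ix_(own, own)][np.triu_indices(len(own), k=1)]
        n_undef = int(np.isnan(intra).sum())
        intra = intra[~np.isnan(intra)]
        if len(own) >= 2 and len(intra):
            mean_intra, max_intra = float(intra.mean()), float(intra.max())
        else:
            mean_intra = max_intra = None
        nn_sp, nn_d = None, None
        for other in species:
            if other == sp:
                continue
            block = m.d[np.ix_(own, idx_by_sp[other])]
            block = block[~np.isnan(block)]
            if not block.size:
                continue
            val = float(block.min() if nn_semantics == "min" else block.mean())
            # ties broken lexicographically by species name (sorted loop order)
            if nn_d is None or val < nn_d:
                nn_sp, nn_d = other, val
        gap = (max_intra < nn_d) if (max_intra is not None and nn_d is not None) else None
        out.append(
            SpeciesDistanceSummary(
                species=sp,
                n=len(own),
                mean_intra=mean_intra,
                max_intra=max_intra,
                nn_species=nn_sp,
                nn_distance=nn_d,
                gap_present=gap,
                n_undefined_pairs=n_undef,
            )
        )
    return out


def gap_scatter(summaries: list[SpeciesDistanceSummary]) -> pd.DataFrame:
    """Barcode-gap scatter table: one row per species with a defined max_intra.

    Points above the 1:1 line (nn_distance > max_intra) exhibit a gap.
    """
    rows = [
        (s.species, s.max_intra, s.nn_distance, s.gap_present)
        for s in summaries
        if s.max_intra is not None and s.nn_distance is not None
    ]
    return pd.DataFrame(
        rows, columns=["species", "max_intra", "nn_distance", "gap_present"]
    )


def plot_gap_scatter(summaries: list[SpeciesDistanceSummary], path) -> None:
    """Max-intra vs nearest-neighbour scatter (percent) with the 1:1 line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = gap_scatter(summaries)
    fig, ax = plt.subplots(figsize=(5, 5))
    x = df["max_intra"] * 100
    y = df["nn_distance"] * 100
    ax.scatter(x, y, c=["k" if not g else "tab:blue" for g in df["gap_present"]])
    lim = max(1.0, float(max(x.max(), y.max())) * 1.1) if len(df) else 1.0
    ax.plot([0, lim], [0, lim], "k-", lw=0.8)
    ax.set_xlabel("Maximum intraspecific distance (%)")
    ax.set_ylabel("Nearest-neighbour distance (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
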