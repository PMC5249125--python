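"""The decision layer of the library audit.

Three curation instruments sit on top of the distance/tree/OTU structures:

* misidentification calls — specimens whose barcode places them with a
  different (usually congeneric) species than their field label;
* OTU review — reclassifying discordant OTUs whose conflict is explained by
  interim (provisional) names or by one-or-two mislabelled records;
* A-E reliability grades per species, from externally confirmed concordance
  (A) to conflicting assignment (E), following the Costa et al. ranking
  criteria, with reference matches supplied as an offline table.

A species whose specimens split into two or more strongly supported,
deeply diverged sub-clusters can be divided into provisional taxa
("Species 1", "Species 2") that are then graded independently.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cluster import OtuCluster, TreeWithSupport
from .distance import DistanceMatrix, SpeciesDistanceSummary


class GradingError(ValueError):
    """Raised when no grading rule can be evaluated for a species."""


# ---------------------------------------------------------------------------
# misidentification calls


@dataclass
class MisidentificationCall:
    specimen_id: str
    morph_label: str
    barcode_label: str
    otu_id: str
    division: str
    dist_to_proposed: float
    dist_to_own: Optional[float]
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.morph_label == self.barcode_label:
            raise ValueError("a call must propose a different label")


def _majority_label(otu: OtuCluster, labels: dict[str, str]) -> str:
    counts: dict[str, int] = {}
    for sid in otu.members:
        counts[labels[sid]] = counts.get(labels[sid], 0) + 1
    return max(sorted(counts), key=lambda sp: counts[sp])


def flag_misidentifications(
    otus: list[OtuCluster],
    m: DistanceMatrix,
    labels: dict[str, str],
    divisions: Optional[dict[str, str]] = None,
) -> list[MisidentificationCall]:
    """Call specimens whose OTU majority label contradicts their field label.

    A specimen is called iff (a) the majority label of its OTU differs from
    its own label, and (b) its mean distance to the majority-label specimens
    is smaller than its mean distance to its own-label specimens.  When the
    specimen's own label has no other representative, rule (a) alone decides
    and the call is flagged low-confidence.
    """
    divisions = divisions or {}
    idx = {sid: k for k, sid in enumerate(m.ids)}
    by_label: dict[str, list[int]] = {}
    for sid in m.ids:
        by_label.setdefault(labels[sid], []).append(idx[sid])

    calls = []
    for otu in otus:
        maj = _majority_label(otu, labels)
        for sid in otu.members:
            own = labels[sid]
            if own == maj:
                continue
            i = idx[sid]
            maj_idx = [k for k in by_label.get(maj, []) if k != i]
            own_idx = [k for k in by_label.get(own, []) if k != i]
            if not maj_idx:
                continue
            d_maj = float(np.nanmean(m.d[i, maj_idx]))
            if own_idx:
                d_own = float(np.nanmean(m.d[i, own_idx]))
                if not d_maj < d_own:
                    continue
                low = False
            else:
                d_own, low = None, True
            calls.append(
                MisidentificationCall(
                    specimen_id=sid,
                    morph_label=own,
                    barcode_label=maj,
                    otu_id=otu.otu_id,
                    division=divisions.get(sid, ""),
                    dist_to_proposed=d_maj,
                    dist_to_own=d_own,
                    low_confidence=low,
                )
            )
    calls.sort(key=lambda c: (c.barcode_label, c.morph_label, c.division, c.specimen_id))
    return calls


def misid_report(
    calls: list[MisidentificationCall],
    labels: dict[str, str],
    divisions: dict[str, str],
) -> pd.DataFrame:
    """Misidentification table grouped by proposed label, field label, division.

    ``n_misid / n_total`` mirrors the conventional "x/y" presentation where
    y counts all barcoded individuals carrying the field label in that
    division.
    """
    totals: dict[tuple[str, str], int] = {}
    for sid, sp in labels.items():
        key = (sp, divisions.get(sid, ""))
        totals[key] = totals.get(key, 0) + 1
    grouped: dict[tuple[str, str, str], int] = {}
    for c in calls:
        key = (c.barcode_label, c.morph_label, c.division)
        grouped[key] = grouped.get(key, 0) + 1
    rows = [
        (bc, mo, dv, n, totals.get((mo, dv), 0))
        for (bc, mo, dv), n in sorted(grouped.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["barcode_label", "morph_label", "division", "n_misid", "n_total"],
    )


def apply_relabelling(calls: list[MisidentificationCall]) -> dict[str, str]:
    """specimen_id -> corrected label for every call (the curation step)."""
    return {c.specimen_id: c.barcode_label for c in calls}


# ---------------------------------------------------------------------------
# OTU review

#: a label is provisional (interim) iff its epithet part is "sp."-like or a
#: numbered placeholder: "Mustelus sp.", "Mustelus sp. zpl 00058",
#: "Raja sp. A", "Dipturus oxyrinchus sp1"
_INTERIM_RE = re.compile(r"\bsp\.?(\s+\S.*)?$|\bsp\d+\b", re.IGNORECASE)


def is_interim_name(label: str) -> bool:
    parts = label.split(None, 1)
    if len(parts) < 2:
        return True  # bare genus counts as provisional
    return bool(_INTERIM_RE.search(parts[1]))


def _genus(label: str) -> str:
    return label.split()[0] if label.split() else label


@dataclass
class ReviewedOtu:
    otu: OtuCluster
    post_review_status: str  # concordant | discordant
    reasons: list[str] = field(default_factory=list)
    canonical_species: Optional[str] = None
    suspected_misids: list[str] = field(default_factory=list)


def review_otu(
    otu: OtuCluster,
    labels: dict[str, str],
    minority_k: int = 2,
) -> ReviewedOtu:
    """Apply the post-hoc concordance review rules to one OTU.

    Rules fire in order: (1) interim names fold into the single congeneric
    binomial present in the OTU; (2) if afterwards all but at most
    ``minority_k`` records share one species, the OTU is concordant with the
    minority flagged as suspected misidentifications; (3) otherwise it stays
    discordant (multi_species).
    """
    counts: dict[str, int] = {}
    for sid in otu.members:
        counts[labels[sid]] = counts.get(labels[sid], 0) + 1
    reasons: list[str] = []

    full = [sp for sp in counts if not is_interim_name(sp)]
    folded = dict(counts)
    for sp in list(folded):
        if is_interim_name(sp):
            congeners = [f for f in full if _genus(f) == _genus(sp)]
            if len(congeners) == 1:
                folded[congeners[0]] = folded.get(congeners[0], 0) + folded.pop(sp)
                if "interim_name" not in reasons:
                    reasons.append("interim_name")

    if len(folded) == 1:
        return ReviewedOtu(otu, "concordant", reasons, next(iter(folded)))

    majority = max(sorted(folded), key=lambda sp: folded[sp])
    minority_n = sum(n for sp, n in folded.items() if sp != majority)
    if minority_n <= minority_k:
        reasons.append("minority_misid")
        suspects = [
            sid for sid in otu.members if labels[sid] != majority
        ]
        return ReviewedOtu(otu, "concordant", reasons, majority, suspects)

    reasons.append("multi_species")
    return ReviewedOtu(otu, "discordant", reasons)


# ---------------------------------------------------------------------------
# grading


@dataclass
class ReferenceMatch:
    """One offline reference-database query result for a species."""

    species: str
    match_found: bool
    matched_species: Optional[str] = None
    matched_max_divergence: Optional[float] = None  # fraction
    matched_monophyletic: bool = True


@dataclass
class GradeAssignment:
    species: str
    grade: str
    rationale: str


DIVERGENCE_CUTOFF = 0.02  # the 2% sequence-divergence criterion of grades A-C


def assign_grade(
    species: str,
    summary: SpeciesDistanceSummary,
    cohesion: dict,
    ref: Optional[ReferenceMatch] = None,
) -> GradeAssignment:
    """Attribute one A-E taxonomic-reliability grade; first matching rule wins.

    E  reference match names a different species, or the matched species is
       para/polyphyletic against the reference;
    A  reference match to the same species, cohesive, divergence <= 2%;
    C  reference match to the same species but divergence > 2% (sub-optimal
       concordance), or no match, n >= 3, cohesive, max intraspecific > 2%;
    B  no reference match, n >= 3, cohesive, max intraspecific <= 2%;
    D  1-2 specimens and no reference match.
    """
    n = summary.n
    cohesive = bool(cohesion.get("cohesive", False))
    if ref is not None and ref.match_found:
        if ref.matched_species != species:
            return GradeAssignment(
                species, "E", f"reference match names {ref.matched_species!r}"
            )
        if not ref.matched_monophyletic or not cohesive:
            return GradeAssignment(
                species, "E", "matched species is para/polyphyletic against reference"
            )
        div = ref.matched_max_divergence
        if div is not None and div > DIVERGENCE_CUTOFF:
            return GradeAssignment(
                species,
                "C",
                f"reference match to self but divergence {div:.3f} > 2%",
            )
        return GradeAssignment(
            species, "A", "reference match to self, cohesive, divergence <= 2%"
        )
    # no external match available
    if n >= 3 and cohesive:
        if summary.max_intra is not None and summary.max_intra > DIVERGENCE_CUTOFF:
            return GradeAssignment(
                species,
                "C",
                f"cohesive but max intraspecific {summary.max_intra:.3f} > 2%",
            )
        return GradeAssignment(
            species, "B", "internal concordance: n >= 3, cohesive, <= 2% divergence"
        )
    if n <= 2:
        return GradeAssignment(
            species, "D", "insufficient data: 1-2 specimens, no reference match"
        )
    raise GradingError(
        f"{species}: n={n}, cohesive={cohesive}, no reference match — "
        "no grading rule applies"
    )


# ---------------------------------------------------------------------------
# sub-cluster splitting


@dataclass
class SubClusterSplit:
    species: str
    groups: list[list[str]]
    provisional_labels: dict[str, str]
    supports: list[Optional[float]]
    n_substitutions: Optional[int]
    percent_divergence: Optional[float]


def sub_cluster_split(
    species: str,
    tree: TreeWithSupport,
    labels: dict[str, str],
    m: DistanceMatrix,
    min_support: float = 95.0,
) -> Optional[SubClusterSplit]:
    """Split a non-cohesive species into strongly supported provisional taxa.

    Returns None (no-op) when the species is cohesive as a single label or
    when no partition into >= 2 fully supported pure sub-clusters exists.
    Groups are renamed "<species> 1", "<species> 2"... by decreasing size;
    the minimum pairwise mismatch count between the two closest groups is
    reported as the differentiating substitution count.
    """
    members = frozenset(s for s, sp in labels.items() if sp == species)
    if len(members) < 2:
        return None
    all_leaves = frozenset(tree.leaves())
    candidates = []
    for _, side, sup in tree.bipartitions():
        for part in (side, all_leaves - side):
            if part and part < members:
                candidates.append((part, sup))
    if any(side == members for _, side, _ in tree.bipartitions()) or any(
        all_leaves - side == members for _, side, _ in tree.bipartitions()
    ):
        return None  # cohesive as a single label
    # maximal pure sub-clusters
    candidates.sort(key=lambda cs: -len(cs[0]))
    groups: list[tuple[frozenset, Optional[float]]] = []
    covered: set = set()
    for part, sup in candidates:
        if part & covered:
            continue
        groups.append((part, sup))
        covered |= part
    if covered != members or len(groups) < 2:
        return None
    for part, sup in groups:
        if len(part) >= 2 and (sup is None or sup < min_support):
            return None
    ordered = sorted(groups, key=lambda g: (-len(g[0]), min(g[0])))
    prov: dict[str, str] = {}
    out_groups = []
    for k, (part, _) in enumerate(ordered, start=1):
        out_groups.append(sorted(part))
        for sid in part:
            prov[sid] = f"{species} {k}"
    # substitution distance between the two closest groups
    idx = {sid: i for i, sid in enumerate(m.ids)}
    best = None
    for a in range(len(out_groups)):
        for b in range(a + 1, len(out_groups)):
            for sa in out_groups[a]:
                for sb in out_groups[b]:
                    i, j = idx[sa], idx[sb]
                    if np.isnan(m.d[i, j]):
                        continue
                    subs = int(round(m.d[i, j] * m.sites[i, j]))
                    if best is None or subs < best[0]:
                        best = (subs, float(m.d[i, j]) * 100)
    return SubClusterSplit(
        species=species,
        groups=out_groups,
        provisional_labels=prov,
        supports=[s for _, s in ordered],
        n_substitutions=best[0] if best else None,
        percent_divergence=best[1] if best else None,
    )
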