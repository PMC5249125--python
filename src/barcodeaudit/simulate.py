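"""Synthetic barcode libraries with known ground truth.

The generator emulates the statistical structure a COI reference-library
audit assumes: well-separated species clusters (expected inter-species
p-distance around 8%, with optional sibling pairs far closer), shallow
intraspecific variation (mean pairwise p-distance around 0.3%),
division-private lineages, and injected curation artefacts — label swaps
between congeners, interim ("Genus sp.") names, in-frame stop codons and
upstream sequencing failures.  Every artefact is recorded exactly once in
a truth table so each audit stage can be scored against ground truth.

Substitutions follow a Jukes-Cantor-like scheme (uniform random target
base, positions drawn with replacement, back-mutation possible); the audit
consumes p-distances only, so no rate heterogeneity or codon model is
simulated.  All "clean" sequences are kept free of in-frame stop codons by
construction so the QC exclusion set equals the injected set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import BarcodeLibrary, SpecimenRecord, count_stops, _stop_codons

FAO_DIVISIONS = ["37.1.1", "37.1.3", "37.2.1", "37.2.2", "37.3.1", "37.3.2"]

_BASES = np.array(list("ACGT"))
_STOPS = _stop_codons("vertebrate-mito")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic library draw.

    ``inter_divergence`` is the expected ancestor-to-ancestor p-distance
    averaged over species pairs; ``sibling_pairs`` overrides individual
    pairs (indices into the species list) with a reduced divergence.
    ``intra_theta`` is the expected substitutions per site per specimen
    from its species ancestor, so the expected pairwise intraspecific
    p-distance is about twice this value.
    """

    seed: int = 0
    alignment_length: int = 651
    n_species: int = 10
    n_specimens: int = 10
    species_names: Optional[list[str]] = None
    inter_divergence: float = 0.08
    sibling_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    intra_theta: float = 0.0015
    divisions: list[str] = field(default_factory=lambda: list(FAO_DIVISIONS))
    divisions_per_species: int = 3
    private_lineages: list[tuple[int, str, int]] = field(default_factory=list)
    misid_rate: float = 0.0
    misid_pairs: list[tuple[int, int]] = field(default_factory=list)
    interim_rate: float = 0.0
    stopcodon_rate: float = 0.0
    failure_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.alignment_length % 3:
            raise ValueError("alignment_length must be divisible by 3")
        for r in (
            self.misid_rate,
            self.interim_rate,
            self.stopcodon_rate,
            self.failure_rate,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if not 0.0 < self.inter_divergence <= 0.75:
            raise ValueError("inter_divergence must lie in (0, 0.75]")

    def species(self) -> list[str]:
        if self.species_names is not None:
            if len(self.species_names) != self.n_species:
                raise ValueError("species_names length must equal n_species")
            return list(self.species_names)
        # two species per genus so congeners exist for swap/interim injection
        return [
            f"Genus{i // 2 + 1} species{i + 1}" for i in range(self.n_species)
        ]


@dataclass
class TruthTable:
    """Ground truth of a simulated library."""

    specimens: pd.DataFrame  # one row per generated individual
    species_pairs: pd.DataFrame  # realised ancestor divergences

    def injected_misids(self) -> pd.DataFrame:
        return self.specimens[self.specimens.is_misid]


# ---------------------------------------------------------------------------
# sequence machinery


def _random_stopfree_sequence(rng: np.random.Generator, length: int) -> str:
    codons = []
    while 3 * len(codons) < length:
        codon = "".join(rng.choice(_BASES, size=3))
        if codon not in _STOPS:
            codons.append(codon)
    return "".join(codons)[:length]


def _repair_stops(seq: str, template: str) -> str:
    """Replace any in-frame stop codon with the template's codon."""
    if count_stops(seq, 1, _STOPS) == 0:
        return seq
    out = list(seq)
    for i in range(0, len(seq) - 2, 3):
        if "".join(out[i : i + 3]) in _STOPS:
            out[i : i + 3] = template[i : i + 3]
    return "".join(out)


def _mutate(
    rng: np.random.Generator, seq: str, n_subs: int, template: Optional[str] = None
) -> str:
    """Apply n substitutions at uniform positions (with replacement)."""
    out = list(seq)
    for _ in range(n_subs):
        pos = int(rng.integers(len(out)))
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[int(rng.integers(3))]
    return _repair_stops("".join(out), template or seq)


def _mutate_at(seq: str, changes: Sequence[tuple[int, str]]) -> str:
    out = list(seq)
    for pos, base in changes:
        out[pos] = base
    return "".join(out)


def _inject_stop(rng: np.random.Generator, seq: str) -> str:
    pos = 3 * int(rng.integers(len(seq) // 3))
    return seq[:pos] + "TAA" + seq[pos + 3 :]


def _coalescent_tree(
    rng: np.random.Generator, n: int, inter: float
) -> tuple[dict, np.ndarray, float]:
    """Random ultrametric coalescent-shaped species tree.

    Returns (root node, scaled pairwise divergence matrix, height scale);
    the scale is chosen so the mean pairwise leaf divergence equals
    ``inter``.
    """
    active: list[dict] = [{"height": 0.0, "leaf": i} for i in range(n)]
    heights = np.sort(rng.uniform(0.2, 1.0, size=n - 1))
    for h in heights:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        node = {"height": float(h), "children": [active[i], active[j]]}
        active[i] = node
        del active[j]
    root = active[0]

    def leafset(nd: dict) -> list[int]:
        if "leaf" in nd:
            return [nd["leaf"]]
        return leafset(nd["children"][0]) + leafset(nd["children"][1])

    d = np.zeros((n, n))

    def fill(nd: dict) -> None:
        if "leaf" in nd:
            return
        a, b = (leafset(c) for c in nd["children"])
        for x in a:
            for y in b:
                d[x, y] = d[y, x] = 2 * nd["height"]
        for c in nd["children"]:
            fill(c)

    fill(root)
    iu = np.triu_indices(n, k=1)
    scale = inter / d[iu].mean()
    return root, d * scale, scale


# ---------------------------------------------------------------------------
# the generator


def simulate_library(cfg: SimulationConfig) -> tuple[BarcodeLibrary, TruthTable]:
    """Draw one synthetic library plus its truth table; reproducible by seed."""
    rng = np.random.default_rng(cfg.seed)
    L = cfg.alignment_length
    species = cfg.species()
    S = len(species)
    root = _random_stopfree_sequence(rng, L)

    # species ancestors evolved down a coalescent-shaped tree whose mean
    # pairwise leaf divergence is calibrated to inter_divergence
    if S == 1:
        ancestors: list[str] = [root]
        target = np.zeros((1, 1))
    else:
        tree_root, target, scale = _coalescent_tree(rng, S, cfg.inter_divergence)
        ancestors = [""] * S

        def evolve(node: dict, seq: str) -> None:
            for child in node["children"]:
                blen = (node["height"] - child["height"]) * scale
                cseq = _mutate(rng, seq, rng.poisson(blen * L), template=seq)
                if "leaf" in child:
                    ancestors[child["leaf"]] = cseq
                else:
                    evolve(child, cseq)

        evolve(tree_root, root)
    for a, b, div in cfg.sibling_pairs:
        ancestors[b] = _mutate(
            rng, ancestors[a], rng.poisson(div * L), template=ancestors[a]
        )
        if S > 1:
            target[a, b] = target[b, a] = div

    # division occupancy per species
    occupancy = []
    for s in range(S):
        k = min(cfg.divisions_per_species, len(cfg.divisions))
        occ = sorted(rng.choice(len(cfg.divisions), size=k, replace=False))
        occupancy.append([cfg.divisions[i] for i in occ])
    for s, division, _nmut in cfg.private_lineages:
        if division not in occupancy[s]:
            occupancy[s].append(division)

    private_changes: dict[tuple[int, str], list[tuple[int, str]]] = {}
    for s, division, nmut in cfg.private_lineages:
        positions = rng.choice(L, size=nmut, replace=False)
        changes = []
        for pos in positions:
            cur = ancestors[s][pos]
            alt = [b for b in "ACGT" if b != cur]
            changes.append((int(pos), alt[int(rng.integers(3))]))
        private_changes[(s, division)] = changes

    congener_pairs = cfg.misid_pairs or [
        (i, j)
        for i in range(S)
        for j in range(S)
        if i != j and species[i].split()[0] == species[j].split()[0]
    ]
    misid_target = {a: b for a, b in congener_pairs}

    records, rows = [], []
    hap_registry: dict[int, dict[str, int]] = {s: {} for s in range(S)}
    counter = 0
    for s in range(S):
        occ = occupancy[s]
        for k in range(cfg.n_specimens):
            counter += 1
            sid = f"S{counter:05d}"
            division = occ[int(rng.integers(len(occ)))]
            base = ancestors[s]
            if (s, division) in private_changes:
                base = _repair_stops(
                    _mutate_at(base, private_changes[(s, division)]), ancestors[s]
                )
            seq = _mutate(rng, base, rng.poisson(cfg.intra_theta * L), template=base)
            haps = hap_registry[s]
            if seq not in haps:
                haps[seq] = len(haps) + 1
            true_hap = f"{species[s]}:{haps[seq]}"

            label = species[s]
            is_misid = False
            if cfg.misid_rate > 0 and s in misid_target:
                if rng.random() < cfg.misid_rate:
                    label = species[misid_target[s]]
                    is_misid = True
            is_interim = False
            if not is_misid and cfg.interim_rate > 0 and rng.random() < cfg.interim_rate:
                label = f"{species[s].split()[0]} sp."
                is_interim = True
            has_stop = False
            if cfg.stopcodon_rate > 0 and rng.random() < cfg.stopcodon_rate:
                seq = _inject_stop(rng, seq)
                has_stop = True
            is_failure = cfg.failure_rate > 0 and rng.random() < cfg.failure_rate

            rows.append(
                dict(
                    specimen_id=sid,
                    true_species=species[s],
                    assigned_label=label,
                    is_misid=is_misid,
                    is_interim=is_interim,
                    has_stop=has_stop,
                    is_failure=is_failure,
                    division=division,
                    true_haplotype=true_hap,
                )
            )
            if not is_failure:
                records.append(
                    SpecimenRecord(
                        specimen_id=sid,
                        sequence=seq,
                        morph_label=label,
                        division=division,
                    )
                )

    pair_rows = []
    for i in range(S):
        for j in range(i + 1, S):
            a, b = ancestors[i], ancestors[j]
            realised = sum(x != y for x, y in zip(a, b)) / L
            pair_rows.append(
                dict(
                    species_a=species[i],
                    species_b=species[j],
                    configured=float(target[i, j]) if S > 1 else 0.0,
                    realised=realised,
                )
            )
    truth = TruthTable(
        specimens=pd.DataFrame(rows),
        species_pairs=pd.DataFrame(
            pair_rows,
            columns=["species_a", "species_b", "configured", "realised"],
        ),
    )
    library = BarcodeLibrary(records, alignment_length=L)
    return library, truth


# ---------------------------------------------------------------------------
# canned scenarios


def table1_scenario(seed: int = 11) -> tuple[BarcodeLibrary, TruthTable]:
    """A misidentification batch shaped like a real survey division.

    One congener pair dominates: in the Adriatic division 146 individuals
    carry the first species' field label but 45 of them are really the
    second species (juvenile confusion), alongside correctly labelled
    records of both species and two clean outgroup species — at most 300
    specimens in total.
    """
    species = [
        "Mustelus mustelus",
        "Mustelus punctulatus",
        "Raja clavata",
        "Scyliorhinus canicula",
    ]
    per_division = {
        # (species idx, division): (n correct, [mislabelled-as idx] * count)
        (0, "37.2.1"): 101,
        (1, "37.2.1"): 105,  # 60 correct + 45 mislabelled as species 0
        (2, "37.1.1"): 20,
        (3, "37.2.1"): 20,
    }
    # built directly (not via simulate_library) so per-division counts are exact
    rng = np.random.default_rng(seed)
    L, theta = 651, 0.0015
    root = _random_stopfree_sequence(rng, L)
    ancestors = [
        _mutate(rng, root, rng.poisson(0.04 * L), template=root) for _ in species
    ]
    records, rows = [], []
    counter = 0
    hap_registry: dict[int, dict[str, int]] = {s: {} for s in range(4)}

    def emit(s: int, division: str, label_idx: int) -> None:
        nonlocal counter
        counter += 1
        sid = f"S{counter:05d}"
        seq = _mutate(
            rng, ancestors[s], rng.poisson(theta * L), template=ancestors[s]
        )
        haps = hap_registry[s]
        if seq not in haps:
            haps[seq] = len(haps) + 1
        rows.append(
            dict(
                specimen_id=sid,
                true_species=species[s],
                assigned_label=species[label_idx],
                is_misid=label_idx != s,
                is_interim=False,
                has_stop=False,
                is_failure=False,
                division=division,
                true_haplotype=f"{species[s]}:{haps[seq]}",
            )
        )
        records.append(
            SpecimenRecord(
                specimen_id=sid,
                sequence=seq,
                morph_label=species[label_idx],
                division=division,
            )
        )

    for _ in range(per_division[(0, "37.2.1")]):
        emit(0, "37.2.1", 0)
    for k in range(per_division[(1, "37.2.1")]):
        emit(1, "37.2.1", 0 if k < 45 else 1)  # 45 swaps, 30 correct
    for _ in range(per_division[(2, "37.1.1")]):
        emit(2, "37.1.1", 2)
    for _ in range(per_division[(3, "37.2.1")]):
        emit(3, "37.2.1", 3)

    pair_rows = [
        dict(
            species_a=species[i],
            species_b=species[j],
            configured=0.08,
            realised=sum(x != y for x, y in zip(ancestors[i], ancestors[j])) / L,
        )
        for i in range(4)
        for j in range(i + 1, 4)
    ]
    return (
        BarcodeLibrary(records, alignment_length=L),
        TruthTable(pd.DataFrame(rows), pd.DataFrame(pair_rows)),
    )


def _haplotype_library(
    species: str,
    seed: int,
    haps: list[tuple[list[tuple[int, str]], list[str]]],
    length: int = 651,
) -> tuple[BarcodeLibrary, TruthTable]:
    """Build a library from explicit haplotype definitions.

    ``haps`` lists (mutations from the base sequence, divisions of the
    sampled specimens); haplotype frequency is the division-list length.
    """
    rng = np.random.default_rng(seed)
    base = _random_stopfree_sequence(rng, length)
    used_positions = {p for muts, _ in haps for p, _ in muts}
    assert len(used_positions) <= length
    records, rows = [], []
    counter = 0
    seen: dict[str, int] = {}
    for hap_no, (muts, divisions) in enumerate(haps, start=1):
        seq = base
        for pos, alt in muts:
            options = [alt] if alt != "*" else [b for b in "ACGT" if b != base[pos]]
            for option in options:
                cand = seq[:pos] + option + seq[pos + 1 :]
                codon_start = 3 * (pos // 3)
                if cand[codon_start : codon_start + 3] not in _STOPS:
                    seq = cand
                    break
            else:
                raise ValueError(f"cannot place a stop-free mutation at {pos}")
        if seq in seen:
            raise ValueError(f"haplotypes {seen[seq]} and {hap_no} collide")
        seen[seq] = hap_no
        for division in divisions:
            counter += 1
            sid = f"S{counter:05d}"
            rows.append(
                dict(
                    specimen_id=sid,
                    true_species=species,
                    assigned_label=species,
                    is_misid=False,
                    is_interim=False,
                    has_stop=False,
                    is_failure=False,
                    division=division,
                    true_haplotype=f"{species}:{hap_no}",
                )
            )
            records.append(
                SpecimenRecord(
                    specimen_id=sid,
                    sequence=seq,
                    morph_label=species,
                    division=division,
                )
            )
    return (
        BarcodeLibrary(records, alignment_length=length),
        TruthTable(
            pd.DataFrame(rows),
            pd.DataFrame(columns=["species_a", "species_b", "configured", "realised"]),
        ),
    )


BALEARIC, SARDINIA, ADRIATIC, IONIAN, LEVANT = (
    "37.1.1",
    "37.1.3",
    "37.2.1",
    "37.2.2",
    "37.3.2",
)

FIG4_STYLES = ("miraletus", "asterias", "polystigma", "radula", "marmorata")


def fig4_scenario(style: str, seed: int = 4) -> tuple[BarcodeLibrary, TruthTable]:
    """Canned per-species network scenarios with known qualitative structure.

    miraletus — 8 haplotypes, exactly one private (all its samples from the
    Levant); radula — a 2-specimen Levant haplotype three mutations from
    the rest; polystigma — 5 haplotypes with one private to the Adriatic;
    asterias — three haplotype groups partitioned by division sets (plus a
    singleton); marmorata — three two-haplotype groups with division-set
    structure.
    """
    if style not in FIG4_STYLES:
        raise ValueError(f"unknown scenario style {style!r}; choose from {FIG4_STYLES}")
    if style == "miraletus":
        # star around hap1; hap8 (lowest frequency) private to the Levant
        haps = [
            ([], [BALEARIC] * 5 + [SARDINIA] * 4 + [IONIAN] * 3),
            ([(10, "*")], [BALEARIC] * 4 + [SARDINIA] * 2),
            ([(20, "*")], [SARDINIA] * 3 + [IONIAN] * 2),
            ([(30, "*")], [BALEARIC] * 2 + [IONIAN] * 2),
            ([(40, "*")], [BALEARIC, SARDINIA, IONIAN]),
            ([(50, "*")], [SARDINIA, IONIAN, BALEARIC]),
            ([(60, "*")], [BALEARIC, IONIAN]  + [SARDINIA]),
            ([(70, "*")], [LEVANT] * 2),
        ]
        return _haplotype_library("Raja miraletus", seed, haps)
    if style == "radula":
        haps = [
            ([], [BALEARIC] * 6),
            ([(12, "*")], [BALEARIC] * 4),
            ([(24, "*")], [BALEARIC] * 3),
            ([(36, "*")], [BALEARIC] * 2),
            ([(48, "*")], [BALEARIC] * 2),
            ([(60, "*"), (63, "*"), (66, "*")], [LEVANT] * 2),
        ]
        return _haplotype_library("Raja radula", seed, haps)
    if style == "polystigma":
        shared = [BALEARIC, SARDINIA, IONIAN]
        haps = [
            ([], [BALEARIC] * 4 + [SARDINIA] * 3 + [IONIAN] * 2),
            ([(15, "*")], shared),
            ([(27, "*")], [BALEARIC, IONIAN] + [SARDINIA]),
            ([(39, "*")], [SARDINIA, BALEARIC]),
            ([(51, "*")], [ADRIATIC] * 2),
        ]
        return _haplotype_library("Raja polystigma", seed, haps)
    if style == "asterias":
        haps = [
            # group 1: Sardinia + Ionian
            ([], [SARDINIA] * 4 + [IONIAN] * 3),
            ([(9, "*")], [SARDINIA] * 2 + [IONIAN]),
            ([(18, "*")], [IONIAN] * 2 + [SARDINIA]),
            # group 2: Balearic (two private haplotypes)
            ([(30, "*"), (33, "*")], [BALEARIC] * 3),
            ([(30, "*"), (33, "*"), (45, "*")], [BALEARIC] * 2),
            # group 3: Adriatic
            ([(60, "*"), (63, "*")], [ADRIATIC] * 3),
            ([(60, "*"), (63, "*"), (72, "*")], [ADRIATIC] * 2),
            ([(60, "*"), (63, "*"), (81, "*")], [ADRIATIC] * 2),
            ([(60, "*"), (63, "*"), (90, "*")], [ADRIATIC]),
            # singleton from the Strait of Sicily (Ionian division)
            ([(60, "*"), (63, "*"), (99, "*")], [IONIAN]),
        ]
        return _haplotype_library("Raja asterias", seed, haps)
    # marmorata: three haplotype groups partitioned by division sets
    haps = [
        ([], [BALEARIC] * 3 + [SARDINIA] * 2 + [IONIAN] * 2),
        ([(9, "*")], [BALEARIC, SARDINIA, IONIAN]),
        ([(21, "*"), (24, "*")], [IONIAN] * 2 + [ADRIATIC] * 2),
        ([(21, "*"), (24, "*"), (33, "*")], [ADRIATIC, IONIAN]),
        ([(45, "*"), (48, "*"), (51, "*")], [LEVANT] * 2),
        ([(45, "*"), (48, "*"), (51, "*"), (60, "*")], [LEVANT]),
    ]
    return _haplotype_library("Torpedo marmorata", seed, haps)
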