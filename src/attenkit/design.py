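"""Constrained enumeration and assembly of 5′ UTR attenuator hairpins.

Every attenuator insert shares a fixed architecture: a constant 7-nt
"base arm" (GCGGCCG, seven of the eight NotI recognition bases, which
keeps the insert clonable and thermally anchors the stem), a variable
G/C-rich stem of up to 11 nt carrying a prescribed number of A/T bases,
a constant non-complementary TATACT loop, and the reverse complements
of stem and arm.  Grading the library downward is done by trimming the
loop-adjacent stem pair one at a time, which shortens the helix and
raises (destabilizes) the folding free energy in small steps.

The full pipeline — enumerate full-length stems, derive trimmed
variants, drop duplicates and all-G/C stems, assemble and score — is
:func:`build_library`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from . import thermo
from .thermo import EnergyModel, PairingMap, revcomp

__all__ = [
    "BASE_ARM",
    "LOOP",
    "DEFAULT_FORBIDDEN_MOTIFS",
    "StemSequence",
    "DesignConstraints",
    "HairpinStructure",
    "enumerate_stems",
    "is_self_complementary",
    "derive_trimmed_variants",
    "dedup_and_filter",
    "assemble_hairpin",
    "build_library",
    "library_diagnostics",
    "REFERENCE_PIPELINE",
    "validate_against_constraints",
    "library_to_tsv",
    "library_to_fasta",
]

#: Constant outer stem arm: seven of the eight NotI site bases.
BASE_ARM = "GCGGCCG"
#: Constant non-complementary hairpin loop.
LOOP = "TATACT"

#: Recognition sites of the enzymes the cloning geometry relies on.
DEFAULT_FORBIDDEN_MOTIFS = (
    "ACCGGT",  # AgeI
    "GCGGCCGC",  # NotI
    "CCTGCAGG",  # SbfI
    "GAATTC",  # EcoRI
    "CTCGAG",  # XhoI
)


@dataclass(frozen=True)
class StemSequence:
    """A candidate variable-stem sequence (5′ arm only)."""

    bases: str
    parent_id: Optional[str] = None
    trim_depth: int = 0

    def __post_init__(self) -> None:
        if any(b not in "ACGT" for b in self.bases):
            raise ValueError(f"stem must be ACGT, got {self.bases!r}")

    @property
    def length(self) -> int:
        return len(self.bases)

    @property
    def at_count(self) -> int:
        return sum(1 for b in self.bases if b in "AT")


@dataclass(frozen=True)
class DesignConstraints:
    """Knobs of the stem enumeration and screening stages.

    ``self_comp_window`` of ``None`` disables the self-complementarity
    screen; an empty ``forbidden_motifs`` disables motif screening.
    """

    stem_length_max: int = 11
    at_pairs_required: int = 1
    self_comp_window: Optional[int] = 4
    forbidden_motifs: tuple[str, ...] = DEFAULT_FORBIDDEN_MOTIFS
    trim_floor: int = 1
    dg_window: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not (self.stem_length_max >= self.trim_floor >= 1):
            raise ValueError("need stem_length_max >= trim_floor >= 1")
        if self.self_comp_window is not None and self.self_comp_window < 2:
            raise ValueError("self_comp_window must be >= 2")
        if self.at_pairs_required > self.stem_length_max:
            raise ValueError("more A/T pairs required than stem positions")
        if self.at_pairs_required < 0:
            raise ValueError("at_pairs_required must be >= 0")


@dataclass(frozen=True)
class HairpinStructure:
    """A fully assembled attenuator insert with its intended pairing."""

    insert_sequence: str
    stem: StemSequence
    pairing: PairingMap
    base_arm: str = BASE_ARM
    loop: str = LOOP
    delta_g: Optional[float] = None
    id: Optional[str] = None

    @property
    def total_length(self) -> int:
        return len(self.insert_sequence)

    @property
    def stem_pair_count(self) -> int:
        return len(self.base_arm) + self.stem.length


def is_self_complementary(stem: StemSequence | str, window: int = 4) -> bool:
    """True if the stem can fold back on itself.

    Checks whether any substring of length ≥ ``window`` has its reverse
    complement present downstream (or upstream) at a separation that
    leaves an intramolecular loop of ≥ 3 nt.  Such stems would compete
    with the intended hairpin geometry and are screened out.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    s = stem.bases if isinstance(stem, StemSequence) else stem.upper()
    n = len(s)
    w = window
    # a match of length > window necessarily contains a length-window match
    for i in range(n - w + 1):
        target = revcomp(s[i : i + w])
        start = i + w + 3  # gap of >= 3 between the paired blocks
        j = s.find(target, start)
        if j != -1:
            return True
    return False


def _has_forbidden_motif(seq: str, motifs: Sequence[str]) -> bool:
    rc = revcomp(seq)
    return any(m in seq or m in rc for m in motifs)


def enumerate_stems(constraints: DesignConstraints) -> list[StemSequence]:
    """Enumerate full-length stems satisfying every active constraint.

    Returns all stems of length ``stem_length_max`` with exactly
    ``at_pairs_required`` A/T bases, no forbidden motif on either
    strand, and no self-complementarity, in lexicographic order.
    """
    L = constraints.stem_length_max
    k = constraints.at_pairs_required
    out: list[StemSequence] = []
    for at_positions in itertools.combinations(range(L), k):
        pos = set(at_positions)
        choice_sets = [("A", "T") if i in pos else ("C", "G") for i in range(L)]
        for combo in itertools.product(*choice_sets):
            seq = "".join(combo)
            if constraints.forbidden_motifs and _has_forbidden_motif(
                seq, constraints.forbidden_motifs
            ):
                continue
            if constraints.self_comp_window is not None and is_self_complementary(
                seq, constraints.self_comp_window
            ):
                continue
            out.append(StemSequence(seq))
    out.sort(key=lambda s: s.bases)
    return out


def derive_trimmed_variants(
    stem: StemSequence, floor: int = 1
) -> list[StemSequence]:
    """Lower-stability variants made by deleting the loop-adjacent pair.

    The loop is the innermost element of the hairpin, so trimming the
    "innermost nucleotide pair" removes the 3′-most base of the 5′ stem
    arm (its partner disappears implicitly on assembly).  Variants run
    from one deletion down to ``floor`` nt; the original is excluded.
    """
    if stem.length < floor:
        raise ValueError("stem shorter than the trim floor")
    parent = stem.bases
    return [
        StemSequence(parent[:length], parent_id=parent, trim_depth=stem.length - length)
        for length in range(stem.length - 1, floor - 1, -1)
    ]


def dedup_and_filter(
    stems: Iterable[StemSequence], constraints: DesignConstraints | None = None
) -> list[StemSequence]:
    """Drop exact duplicate stems and stems with no A/T base.

    All-G/C stems are removed because an uninterrupted G/C helix folds
    far outside the useful attenuation range and defeats the
    composition-uniformity goal of the single A/T pair.  Among
    duplicates the entry with the lexicographically first provenance
    (parent id, then trim depth) is kept; output order is stable.
    """
    best: dict[str, StemSequence] = {}
    order: list[str] = []
    for s in stems:
        if s.at_count == 0:
            continue
        key = s.bases
        if key not in best:
            best[key] = s
            order.append(key)
        else:
            incumbent = best[key]
            if (s.parent_id or s.bases, s.trim_depth) < (
                incumbent.parent_id or incumbent.bases,
                incumbent.trim_depth,
            ):
                best[key] = s
    return [best[k] for k in order]


def assemble_hairpin(stem: StemSequence | str) -> HairpinStructure:
    """Assemble the full insert around ``stem`` with its intended pairing.

    The insert is ``base_arm + stem + loop + revcomp(stem) +
    revcomp(base_arm)``; position i of the 5′ half pairs with its mirror
    partner, and the loop stays unpaired.
    """
    if isinstance(stem, str):
        stem = StemSequence(stem.upper())
    five_prime = BASE_ARM + stem.bases
    insert = five_prime + LOOP + revcomp(five_prime)
    n = len(insert)
    n_pairs = len(five_prime)
    pairs = frozenset((i, n - 1 - i) for i in range(n_pairs))
    pairing = PairingMap(
        pairs=pairs, loop_span=(n_pairs, n_pairs + len(LOOP))
    )
    pairing.validate_complementarity(insert)
    return HairpinStructure(insert_sequence=insert, stem=stem, pairing=pairing)


def build_library(
    constraints: DesignConstraints,
    model: EnergyModel | None = None,
) -> list[HairpinStructure]:
    """Run the full design pipeline and return the scored library.

    enumerate → trim-derive → dedup/filter → assemble → score →
    optional ΔG-window filter → sort most stable first.  Identifiers
    "HP001", "HP002", … are assigned by final rank.
    """
    if model is None:
        model = EnergyModel.load("RNA")
    full = enumerate_stems(constraints)
    pool: list[StemSequence] = []
    for stem in full:
        pool.append(stem)
        if stem.length > constraints.trim_floor:
            pool.extend(derive_trimmed_variants(stem, constraints.trim_floor))
    kept = dedup_and_filter(pool, constraints)
    scored: list[HairpinStructure] = []
    for stem in kept:
        hp = assemble_hairpin(stem)
        dg = thermo.hairpin_dG(hp, model)
        if constraints.dg_window is not None:
            lo, hi = sorted(constraints.dg_window)
            if not (lo <= dg <= hi):
                continue
        scored.append(replace(hp, delta_g=dg))
    scored.sort(key=lambda h: (h.delta_g, h.insert_sequence))
    width = max(3, len(str(len(scored))))
    return [
        replace(h, id=f"HP{rank + 1:0{width}d}") for rank, h in enumerate(scored)
    ]


def validate_against_constraints(
    stem: StemSequence, constraints: DesignConstraints
) -> list[str]:
    """Independent post-hoc check of one stem against the constraint list.

    Returns a list of violated-constraint descriptions (empty = valid).
    Full-length stems must carry exactly the required A/T count; trimmed
    stems may carry fewer but never zero.
    """
    problems: list[str] = []
    if stem.length > constraints.stem_length_max:
        problems.append("stem longer than stem_length_max")
    if stem.length < constraints.trim_floor:
        problems.append("stem shorter than trim_floor")
    if stem.trim_depth == 0 and stem.at_count != constraints.at_pairs_required:
        problems.append("full-length stem with wrong A/T count")
    if stem.at_count == 0:
        problems.append("all-G/C stem")
    if stem.at_count > constraints.at_pairs_required:
        problems.append("more A/T bases than required")
    if constraints.forbidden_motifs and stem.trim_depth == 0:
        if _has_forbidden_motif(stem.bases, constraints.forbidden_motifs):
            problems.append("forbidden motif present")
    if (
        constraints.self_comp_window is not None
        and stem.trim_depth == 0
        and is_self_complementary(stem, constraints.self_comp_window)
    ):
        problems.append("self-complementary stem")
    if stem.parent_id is not None:
        if stem.trim_depth != len(stem.parent_id) - stem.length:
            problems.append("trim_depth inconsistent with parent length")
        if not stem.parent_id.startswith(stem.bases):
            problems.append("stem is not a prefix of its parent")
    return problems


#: Counts and ΔG span reported by the original EGNAS-based pipeline this
#: module re-implements.  Its exact generator configuration (forbidden-
#: motif list, self-complementarity rule, trimming floor) was distributed
#: as supplementary config files and is not fully reconstructible, so
#: these are diagnostic reference points, never assertions.
REFERENCE_PIPELINE = {
    "full_length_stem_count": 1360,
    "library_size_after_trim_dedup": 5729,
    "dg_most_stable_kcal_mol": -48.2,
    "dg_least_stable_kcal_mol": -15.7,
}


def library_diagnostics(
    library: Sequence[HairpinStructure], full_length_count: int
) -> dict[str, dict]:
    """Non-binding comparison of a built library to the reference pipeline.

    Returns, per quantity, this run's value, the reference pipeline's
    value, and the difference — for logging, not for pass/fail.
    """
    scored = [h for h in library if h.delta_g is not None]
    ours = {
        "full_length_stem_count": full_length_count,
        "library_size_after_trim_dedup": len(library),
        "dg_most_stable_kcal_mol": min(h.delta_g for h in scored) if scored else None,
        "dg_least_stable_kcal_mol": max(h.delta_g for h in scored) if scored else None,
    }
    return {
        key: {
            "observed": ours[key],
            "reference": ref,
            "difference": None if ours[key] is None else round(ours[key] - ref, 2),
        }
        for key, ref in REFERENCE_PIPELINE.items()
    }


# ---------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------

_TSV_COLUMNS = (
    "id\tstem\tinsert_sequence\tstem_len\ttotal_len\tat_count\t"
    "delta_g_kcal_mol\tparent_id\ttrim_depth"
)


def library_to_tsv(library: Sequence[HairpinStructure]) -> str:
    lines = [_TSV_COLUMNS]
    for h in library:
        dg = "" if h.delta_g is None else f"{h.delta_g:.2f}"
        lines.append(
            f"{h.id or ''}\t{h.stem.bases}\t{h.insert_sequence}\t"
            f"{h.stem.length}\t{h.total_length}\t{h.stem.at_count}\t"
            f"{dg}\t{h.stem.parent_id or ''}\t{h.stem.trim_depth}"
        )
    return "\n".join(lines) + "\n"


def library_to_fasta(library: Sequence[HairpinStructure]) -> str:
    out = []
    for h in library:
        dg = "" if h.delta_g is None else f" dG={h.delta_g:.2f}"
        out.append(f">{h.id or h.stem.bases}{dg}\n{h.insert_sequence}")
    return "\n".join(out) + "\n"
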