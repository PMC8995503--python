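"""Nearest-neighbor thermodynamic evaluation of designed stem-loops.

The attenuator inserts produced by :mod:`attenkit.design` are perfect
hairpins: a fully base-paired stem closed by a short unpaired loop.  For
such a fixed structure the folding free energy at 37 °C decomposes
additively into stacked base-pair terms, a loop-initiation penalty that
depends only on loop length, and a terminal mismatch of the loop-closing
pair.  This module evaluates that decomposition from packaged parameter
tables and, independently, finds the maximum Watson–Crick pairing of an
arbitrary sequence (a Nussinov-style dynamic program) so a designed stem
can be checked against alternative folds.

The energy model is deliberately restricted to isolated stem-loops: no
bulges, internal loops, multiloops or dangling ends.  Designed inserts
never contain those elements, and keeping the model minimal keeps every
reported number auditable term by term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "EnergyModel",
    "PairingMap",
    "FoldReport",
    "stack_energy",
    "hairpin_dG",
    "max_pairing_fold",
    "verify_intended_fold",
    "complement",
    "revcomp",
]

# T and U are interchangeable on input; pairing is Watson–Crick only.
_COMPLEMENT = {"A": "T", "T": "A", "U": "A", "G": "C", "C": "G"}

#: Jacobson–Stockmayer coefficient for loops longer than the tabulated
#: range: dg(n) = dg(n_max) + _LOOP_EXTRAPOLATION * ln(n / n_max).
_LOOP_EXTRAPOLATION = 1.07856


class ParameterMissingError(KeyError):
    """A nearest-neighbor table has no entry for the requested stack."""


class InvalidStructureError(ValueError):
    """The structure violates the stem-loop preconditions."""


def complement(base: str) -> str:
    try:
        return _COMPLEMENT[base.upper()]
    except KeyError:
        raise ValueError(f"not a nucleotide: {base!r}") from None


def revcomp(seq: str) -> str:
    """Reverse complement, preserving the T/U convention of the input."""
    rc = "".join(complement(b) for b in reversed(seq.upper()))
    if "U" in seq.upper():
        rc = rc.replace("T", "U")
    return rc


def is_watson_crick(a: str, b: str) -> bool:
    return _COMPLEMENT.get(a.upper()) in (b.upper(), {"T": "U", "U": "T"}.get(b.upper()))


def _canonical_stack_code(code: str) -> str:
    rot = code[2:] + code[:2]
    return min(code, rot)


@dataclass(frozen=True)
class EnergyModel:
    """A nearest-neighbor ΔG°37 parameter set for perfect hairpins.

    Parameters are loaded from packaged tab-separated tables whose
    provenance string identifies the published set they transcribe.

    Attributes
    ----------
    stack_table
        Canonical 4-letter stack code → ΔG°37 (kcal/mol).  The code
        ``WXYZ`` reads the top strand 5'-WX-3' over the bottom strand
        5'-YZ-3' (pairs W:Z, X:Y) and is canonicalized under the
        180°-rotation symmetry of a helix.
    hairpin_loop_init
        Loop length (nt, ≥ 3) → initiation penalty (kcal/mol).
    terminal_mismatch_table
        (closing pair, first loop base, last loop base) → kcal/mol.
        ``None``-like empty mapping disables the term.
    terminal_end_penalty
        Penalty applied once if the outermost helix pair is A:T/A:U
        (the standard helix-end penalty of the parameter set).
    nucleic_acid_kind
        "RNA" (default; designs act in mRNA, T is read as U) or "DNA".
    """

    stack_table: Mapping[str, float]
    hairpin_loop_init: Mapping[int, float]
    terminal_mismatch_table: Mapping[tuple[str, str, str], float] = field(
        default_factory=dict
    )
    terminal_end_penalty: float = 0.0
    nucleic_acid_kind: str = "RNA"
    temperature: float = 37.0
    provenance: str = "unspecified"
    use_terminal_mismatch: bool = True

    def __post_init__(self) -> None:
        for code, dg in self.stack_table.items():
            if dg >= 0:
                raise ValueError(f"WC/WC stack {code} must be stabilizing, got {dg}")
        for n, dg in self.hairpin_loop_init.items():
            if n < 3:
                raise ValueError(f"hairpin loops of {n} nt are disallowed")
            if dg <= 0:
                raise ValueError(f"loop initiation for {n} nt must be positive")

    # -- construction -------------------------------------------------
    @classmethod
    def load(
        cls, kind: str = "RNA", *, use_terminal_mismatch: bool = True
    ) -> "EnergyModel":
        """Load the packaged parameter set for ``kind`` ("RNA" or "DNA")."""
        kind = kind.upper()
        if kind not in ("RNA", "DNA"):
            raise ValueError(f"nucleic_acid_kind must be RNA or DNA, got {kind!r}")
        tag = kind.lower()
        stacks = {}
        provenance = "unspecified"
        for ln in _data_lines(f"{tag}_stack_dg37.tsv"):
            if ln.startswith("# provenance:"):
                provenance = ln.split(":", 1)[1].strip()
            elif not ln.startswith(("#", "stack\t")):
                code, dg = ln.split("\t")
                stacks[code] = float(dg)
        loops = {}
        for ln in _data_lines(f"{tag}_hairpin_loop_dg37.tsv"):
            if not ln.startswith(("#", "loop_length")):
                n, dg = ln.split("\t")
                loops[int(n)] = float(dg)
        mismatches: dict[tuple[str, str, str], float] = {}
        end_penalty = 0.0
        for ln in _data_lines(f"{tag}_hairpin_mismatch_dg37.tsv"):
            if ln.startswith("# terminal_end_penalty"):
                end_penalty = float(ln.split("\t")[1])
            elif not ln.startswith(("#", "closing_pair")):
                pair, x, y, dg = ln.split("\t")
                mismatches[(pair, x, y)] = float(dg)
        return cls(
            stack_table=stacks,
            hairpin_loop_init=loops,
            terminal_mismatch_table=mismatches,
            terminal_end_penalty=end_penalty,
            nucleic_acid_kind=kind,
            provenance=provenance,
            use_terminal_mismatch=use_terminal_mismatch,
        )

    # -- helpers ------------------------------------------------------
    def normalize(self, seq: str) -> str:
        """Map a DNA/RNA string onto this model's alphabet."""
        seq = seq.upper()
        if self.nucleic_acid_kind == "RNA":
            return seq.replace("T", "U")
        return seq.replace("U", "T")

    def loop_penalty(self, length: int) -> float:
        if length < 3:
            raise InvalidStructureError(f"hairpin loop of {length} nt is disallowed")
        if length in self.hairpin_loop_init:
            return self.hairpin_loop_init[length]
        n_max = max(self.hairpin_loop_init)
        return self.hairpin_loop_init[n_max] + _LOOP_EXTRAPOLATION * math.log(
            length / n_max
        )


def _data_lines(name: str) -> Iterable[str]:
    text = resources.files("attenkit.data").joinpath(name).read_text()
    for ln in text.splitlines():
        if ln.strip():
            yield ln


def stack_energy(
    upstream_pair: tuple[str, str],
    downstream_pair: tuple[str, str],
    model: EnergyModel,
) -> float:
    """ΔG°37 of ``downstream_pair`` stacked on ``upstream_pair``.

    ``upstream_pair`` is the pair closer to the helix terminus on the
    5' (top) strand; each pair is given as (top-strand base, bottom-strand
    base).  Symmetric under the 180°-rotation equivalence of stacks.
    """
    (a1, b1) = upstream_pair
    (a2, b2) = downstream_pair
    a1, b1, a2, b2 = (model.normalize(x) for x in (a1, b1, a2, b2))
    for a, b in ((a1, b1), (a2, b2)):
        if not is_watson_crick(a, b):
            raise InvalidStructureError(f"{a}:{b} is not a Watson–Crick pair")
    code = _canonical_stack_code(a1 + a2 + b2 + b1)
    try:
        return model.stack_table[code]
    except KeyError:
        raise ParameterMissingError(
            f"no stack parameter for {a1}{a2}/{b2}{b1} (code {code})"
        ) from None


@dataclass(frozen=True)
class PairingMap:
    """A non-crossing set of Watson–Crick pairs over an insert sequence.

    ``pairs`` holds 0-based (i, j) index pairs with i < j; ``loop_span``
    is the half-open interval of unpaired loop bases enclosed by the
    innermost pair (empty for pairings without a unique hairpin loop).
    """

    pairs: frozenset[tuple[int, int]]
    loop_span: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if i >= j:
                raise ValueError(f"pair ({i}, {j}) must have i < j")
            if i in seen or j in seen:
                raise ValueError(f"index reused in pairing at ({i}, {j})")
            seen.update((i, j))
        ordered = sorted(self.pairs)
        for a, (i, j) in enumerate(ordered):
            for k, l in ordered[a + 1 :]:
                if i < k < j < l:
                    raise ValueError(f"crossing pairs ({i},{j}) and ({k},{l})")

    def validate_complementarity(self, sequence: str) -> None:
        sequence = sequence.upper()
        for i, j in self.pairs:
            if not is_watson_crick(sequence[i], sequence[j]):
                raise ValueError(
                    f"pair ({i},{j}) = {sequence[i]}:{sequence[j]} is not Watson–Crick"
                )

    def helices(self) -> list[list[tuple[int, int]]]:
        """Maximal runs of directly stacked pairs, outermost first."""
        out: list[list[tuple[int, int]]] = []
        for i, j in sorted(self.pairs):
            if out and out[-1][-1] == (i - 1, j + 1):
                out[-1].append((i, j))
            else:
                out.append([(i, j)])
        return out


def hairpin_dG(structure, model: EnergyModel) -> float:
    """Folding ΔG°37 (kcal/mol) of a perfect stem-loop at its intended fold.

    Sums stack terms over consecutive stem pairs, adds the loop-length
    initiation penalty and (if the model enables it) the terminal
    mismatch of the loop-closing pair, plus the helix-end penalty when
    the outermost pair is A:U.  ``structure`` must expose
    ``insert_sequence`` and an intended ``pairing`` forming one
    contiguous helix around a loop of ≥ 3 nt.
    """
    seq = model.normalize(structure.insert_sequence)
    pairs = sorted(structure.pairing.pairs)
    if len(pairs) < 2:
        raise InvalidStructureError("a hairpin needs at least 2 stem pairs")
    helices = structure.pairing.helices()
    if len(helices) != 1:
        raise InvalidStructureError("intended fold must be a single contiguous helix")
    inner_i, inner_j = pairs[-1]
    loop_len = inner_j - inner_i - 1
    if loop_len < 3:
        raise InvalidStructureError(f"loop of {loop_len} nt is disallowed")

    dg = 0.0
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        dg += stack_energy((seq[i1], seq[j1]), (seq[i2], seq[j2]), model)
    dg += model.loop_penalty(loop_len)
    if model.use_terminal_mismatch and model.terminal_mismatch_table:
        key = (seq[inner_i] + seq[inner_j], seq[inner_i + 1], seq[inner_j - 1])
        dg += model.terminal_mismatch_table.get(key, 0.0)
    outer_i, outer_j = pairs[0]
    if {seq[outer_i], seq[outer_j]} == {"A", "U"} or {seq[outer_i], seq[outer_j]} == {
        "A",
        "T",
    }:
        dg += model.terminal_end_penalty
    return round(dg, 10)


# ---------------------------------------------------------------------
# Maximum-pairing fold (Nussinov-style dynamic program)
# ---------------------------------------------------------------------

def max_pairing_fold(sequence: str, min_loop: int = 3) -> PairingMap:
    """Maximum-cardinality non-crossing Watson–Crick pairing of ``sequence``.

    Ties on pair count are broken by preferring pairings with more
    stacked adjacencies (which favors long contiguous helices), then by
    the lexicographically smallest pair list, so repeated runs always
    report the same structure.
    """
    seq = sequence.upper().replace("U", "T")
    if any(b not in "ACGT" for b in seq):
        bad = next(b for b in seq if b not in "ACGT")
        raise ValueError(f"invalid nucleotide {bad!r} in sequence")
    n = len(seq)
    if n < min_loop + 2:
        raise ValueError(f"sequence of {n} nt cannot form a loop of ≥ {min_loop}")

    NEG = (-1, -1)
    # best[i][j]: (pairs, stacks) over seq[i..j]; bestp: same, given (i, j) paired.
    best = [[(0, 0)] * n for _ in range(n)]
    bestp = [[NEG] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            if is_watson_crick(seq[i], seq[j]):
                cand = best[i + 1][j - 1] if j - 1 >= i + 1 else (0, 0)
                if j - i - 2 > min_loop and bestp[i + 1][j - 1] != NEG:
                    p, s = bestp[i + 1][j - 1]
                    cand = max(cand, (p, s + 1))
                bestp[i][j] = (cand[0] + 1, cand[1])
            # i unpaired
            opt = best[i + 1][j] if i + 1 <= j else (0, 0)
            # i paired with some k
            for k in range(i + min_loop + 1, j + 1):
                if bestp[i][k] == NEG:
                    continue
                right = best[k + 1][j] if k + 1 <= j else (0, 0)
                cand = (bestp[i][k][0] + right[0], bestp[i][k][1] + right[1])
                if cand > opt:
                    opt = cand
            best[i][j] = opt

    pairs: list[tuple[int, int]] = []

    def trace(i: int, j: int) -> None:
        while i < j:
            target = best[i][j]
            if target == (0, 0):
                return
            chosen = None
            for k in range(i + min_loop + 1, j + 1):
                if bestp[i][k] == NEG:
                    continue
                right = best[k + 1][j] if k + 1 <= j else (0, 0)
                if (bestp[i][k][0] + right[0], bestp[i][k][1] + right[1]) == target:
                    chosen = k
                    break
            if chosen is None:
                i += 1
                continue
            pairs.append((i, chosen))
            trace_paired(i, chosen)
            i = chosen + 1

    def trace_paired(i: int, j: int) -> None:
        # (i, j) already recorded; descend into the enclosed interval
        while True:
            want = (bestp[i][j][0] - 1, bestp[i][j][1])
            if j - 1 < i + 1:
                return
            inner_pair = bestp[i + 1][j - 1]
            if inner_pair != NEG and (inner_pair[0], inner_pair[1] + 1) == want:
                pairs.append((i + 1, j - 1))
                i, j = i + 1, j - 1
                continue
            if best[i + 1][j - 1] == want:
                trace(i + 1, j - 1)
            return

    trace(0, n - 1)
    pairing = sorted(pairs)
    loop_span = (0, 0)
    if pairing:
        inner = max(pairing, key=lambda p: p[0])
        loop_span = (inner[0] + 1, inner[1])
    return PairingMap(pairs=frozenset(pairing), loop_span=loop_span)


@dataclass(frozen=True)
class FoldReport:
    """Outcome of checking a designed hairpin against alternative folds."""

    intended_is_maximal: bool
    intended_pair_count: int
    alternative_pair_count: int
    disjoint_alternative_helix: bool

    def as_records(self) -> list[tuple[str, str]]:
        return [
            ("intended_is_maximal", str(self.intended_is_maximal).lower()),
            ("intended_pair_count", str(self.intended_pair_count)),
            ("alternative_pair_count", str(self.alternative_pair_count)),
            (
                "disjoint_alternative_helix",
                str(self.disjoint_alternative_helix).lower(),
            ),
        ]


def verify_intended_fold(
    structure, *, min_loop: int = 4, helix_window: int = 4
) -> FoldReport:
    """Check that the designed stem, not an alternative fold, dominates.

    Runs :func:`max_pairing_fold` on the insert and reports whether the
    intended stem achieves the maximum pair count, plus whether any
    helix of ≥ ``helix_window`` consecutive pairs disjoint from the
    intended stem can form elsewhere in the insert.

    The maximality check uses a 4-nt minimum loop: under a bare 3-nt
    minimum, a single lone A:U pair can always close the central
    TATACT loop, inflating the alternative count by one even though a
    lone pair over a minimal loop is not a stable competing element.
    """
    intended = structure.pairing.pairs
    fold = max_pairing_fold(structure.insert_sequence, min_loop=min_loop)
    alt_count = len(fold.pairs)
    seq = structure.insert_sequence.upper().replace("U", "T")
    disjoint = _has_disjoint_helix(seq, set(intended), helix_window, min_loop)
    return FoldReport(
        intended_is_maximal=len(intended) >= alt_count,
        intended_pair_count=len(intended),
        alternative_pair_count=alt_count,
        disjoint_alternative_helix=disjoint,
    )


def _has_disjoint_helix(
    seq: str, intended_pairs: set[tuple[int, int]], window: int, min_loop: int
) -> bool:
    """Is there a helix of ≥ ``window`` stacked pairs sharing no pair
    with the intended stem (the same bases in a different register
    count as an alternative)?"""
    n = len(seq)
    for i in range(n - 2 * window - min_loop + 1):
        for j in range(i + 2 * window + min_loop - 1, n):
            # candidate helix: (i, j), (i+1, j-1), ... length `window`
            if any((i + t, j - t) in intended_pairs for t in range(window)):
                continue
            if all(
                is_watson_crick(seq[i + t], seq[j - t]) for t in range(window)
            ):
                return True
    return False
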