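"""Assembly and validation of single-transcript knockdown-replacement
constructs.

A KDR transcript couples an attenuated rescue gene with a
microRNA-adapted shRNA on one mRNA: promoter → 5′ UTR attenuator →
Kozak context → rescue coding sequence → (optionally IRES → reporter)
→ miR-E cassette.  This module concatenates user-supplied parts in
that order into an annotated record and enforces the restriction-site
geometry the cloning strategy depends on: AgeI/NotI receive the
attenuator, NotI/SbfI receive the rescue gene, and EcoRI/XhoI open the
miR-E cassette for the shRNA — so those sites must not occur
internally where they would be cut.

Coordinates are 0-based half-open on the top strand throughout; the
GenBank writer converts to the 1-based closed convention of that
format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .thermo import revcomp

__all__ = [
    "ENZYMES",
    "Part",
    "SiteRule",
    "ConstructPlan",
    "MINIMAL_PLAN",
    "INDUCIBLE_PLAN",
    "assemble_construct",
    "RESCUE_SITE_RULES",
    "SHRNA_SITE_RULES",
    "validate_cloning_sites",
    "find_sites",
]

#: Recognition sequences of the enzymes used in the cloning geometry.
ENZYMES = {
    "AgeI": "ACCGGT",
    "NotI": "GCGGCCGC",
    "SbfI": "CCTGCAGG",
    "EcoRI": "GAATTC",
    "XhoI": "CTCGAG",
}

ROLES = (
    "promoter",
    "attenuator",
    "kozak",
    "rescue",
    "ires",
    "reporter",
    "mirE_cassette",
    "shrna",
    "aux",
)


@dataclass(frozen=True)
class Part:
    """One building block of a construct."""

    name: str
    role: str
    sequence: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown part role {self.role!r}")
        if not self.sequence:
            raise ValueError(f"part {self.name!r} has an empty sequence")
        seq = self.sequence.upper()
        if any(b not in "ACGT" for b in seq):
            raise ValueError(f"part {self.name!r} is not plain ACGT")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class SiteRule:
    """One restriction-site requirement on the assembled construct.

    ``kind`` is "must-be-absent-internal" (the site may not occur inside
    the named part, where a digest would cut the insert) or
    "required-flank" (the site must occur somewhere in the record —
    typically contributed by the junction or backbone).
    """

    enzyme: str
    kind: str
    part_role: Optional[str] = None

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYMES:
            raise ValueError(f"unknown enzyme {self.enzyme!r}")
        if self.kind not in ("must-be-absent-internal", "required-flank"):
            raise ValueError(f"unknown rule kind {self.kind!r}")


#: Internal-site rules implied by the cloning workflow: the rescue gene
#: is delivered through NotI/SbfI and the shRNA through EcoRI/XhoI, so
#: those inserts must not carry the corresponding sites internally.
RESCUE_SITE_RULES = (
    SiteRule("NotI", "must-be-absent-internal", "rescue"),
    SiteRule("SbfI", "must-be-absent-internal", "rescue"),
)
SHRNA_SITE_RULES = (
    SiteRule("EcoRI", "must-be-absent-internal", "shrna"),
    SiteRule("XhoI", "must-be-absent-internal", "shrna"),
)
DEFAULT_SITE_RULES = RESCUE_SITE_RULES + SHRNA_SITE_RULES


@dataclass(frozen=True)
class ConstructPlan:
    """Ordered part roles plus the site rules to enforce."""

    variant: str
    role_order: tuple[str, ...]
    site_rules: tuple[SiteRule, ...] = RESCUE_SITE_RULES


MINIMAL_PLAN = ConstructPlan(
    variant="minimal_constitutive",
    role_order=("promoter", "attenuator", "kozak", "rescue", "mirE_cassette"),
)
INDUCIBLE_PLAN = ConstructPlan(
    variant="inducible_reporter",
    role_order=(
        "promoter",
        "attenuator",
        "kozak",
        "rescue",
        "ires",
        "reporter",
        "mirE_cassette",
    ),
)


def assemble_construct(
    plan: ConstructPlan, parts: Sequence[Part], record_id: str = "construct"
) -> SeqRecord:
    """Concatenate parts in plan order into an annotated record.

    Exactly one part per required role; each part becomes one top-strand
    feature with 0-based half-open coordinates.
    """
    by_role: dict[str, Part] = {}
    for p in parts:
        if p.role in by_role:
            raise ValueError(f"duplicate part for role {p.role!r}")
        by_role[p.role] = p
    missing = [r for r in plan.role_order if r not in by_role]
    if missing:
        raise ValueError(f"missing part(s) for role(s): {', '.join(missing)}")

    seq_parts: list[str] = []
    features: list[SeqFeature] = []
    pos = 0
    for role in plan.role_order:
        part = by_role[role]
        end = pos + len(part.sequence)
        features.append(
            SeqFeature(
                FeatureLocation(pos, end, strand=1),
                type="misc_feature",
                qualifiers={"label": [part.name], "role": [role]},
            )
        )
        seq_parts.append(part.sequence)
        pos = end
    record = SeqRecord(
        Seq("".join(seq_parts)),
        id=record_id,
        name=record_id[:16],
        description=f"pKDR assembly ({plan.variant})",
        features=features,
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "linear"
    return record


def find_sites(sequence: str, recognition: str) -> list[tuple[int, int]]:
    """All occurrences of a recognition site on either strand.

    Returns sorted (start, strand) with 0-based top-strand starts;
    strand is +1 for a top-strand match, −1 for a bottom-strand match.
    A palindromic site (its own reverse complement) reports one hit per
    genomic position, on the + strand.
    """
    seq = sequence.upper()
    site = recognition.upper()
    rc = revcomp(site)
    hits: list[tuple[int, int]] = []
    start = 0
    while (i := seq.find(site, start)) != -1:
        hits.append((i, 1))
        start = i + 1
    if rc != site:
        start = 0
        while (i := seq.find(rc, start)) != -1:
            hits.append((i, -1))
            start = i + 1
    return sorted(hits)


def validate_cloning_sites(
    record: SeqRecord, rules: Iterable[SiteRule] = DEFAULT_SITE_RULES
) -> dict[str, dict]:
    """Check each site rule against an assembled record.

    Reports, per rule, every occurrence coordinate (both strands) and a
    pass/fail flag: internal sites must be absent from the named part's
    span; required-flank sites must occur somewhere in the record.
    """
    seq = str(record.seq)
    spans: dict[str, tuple[int, int]] = {}
    for f in record.features:
        role = (f.qualifiers.get("role") or [None])[0]
        if role is not None:
            spans[role] = (int(f.location.start), int(f.location.end))
    report: dict[str, dict] = {}
    for idx, rule in enumerate(rules):
        site = ENZYMES[rule.enzyme]
        hits = find_sites(seq, site)
        entry: dict = {
            "enzyme": rule.enzyme,
            "recognition": site,
            "kind": rule.kind,
            "part_role": rule.part_role,
            "occurrences": hits,
        }
        if rule.kind == "must-be-absent-internal":
            if rule.part_role is None or rule.part_role not in spans:
                raise ValueError(
                    f"rule for {rule.enzyme} names unknown part {rule.part_role!r}"
                )
            lo, hi = spans[rule.part_role]
            internal = [
                (s, st) for s, st in hits if s >= lo and s + len(site) <= hi
            ]
            entry["violations"] = internal
            entry["passed"] = not internal
        else:
            entry["passed"] = bool(hits)
        report[f"{rule.enzyme}:{rule.kind}:{rule.part_role or '-'}"] = entry
    return report


def report_to_tsv(report: dict[str, dict]) -> str:
    lines = ["rule\tenzyme\tkind\tpart_role\tpassed\toccurrences"]
    for key, entry in report.items():
        occ = ";".join(f"{s}{'+' if st > 0 else '-'}" for s, st in entry["occurrences"])
        lines.append(
            f"{key}\t{entry['enzyme']}\t{entry['kind']}\t"
            f"{entry['part_role'] or '-'}\t{str(entry['passed']).lower()}\t{occ}"
        )
    return "\n".join(lines) + "\n"
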