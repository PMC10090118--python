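"""Species typing from diagnostic positions, motifs and difference profiles.

This is the inferential core of the package.  Within the *Stuckenia*
ITS1--ITS2 locus, five taxa are told apart by a small set of characters:

* *S. vaginata* vs. the *S. pectinata* lineage: a large difference set
  (three indels of 1/1/9 nt plus 16 one-nt and 2 two-nt substitution
  runs), corroborated by the count of strict GCGC motifs (the CfoI
  restriction site: one site in *S. vaginata*, two in the others);
* *S. pectinata* type A vs. type B: five one-nt and one two-nt
  substitution runs;
* *S. macrocarpa* vs. type B: a two-nt state change at a diagnostic
  dinucleotide (nominally alignment positions 102-103);
* *S. chakassiensis* vs. type B: a single T/C substitution (nominally
  position 524).

Hybrids between type B and *S. macrocarpa* show IUPAC additivity: at both
diagnostic dinucleotide positions the sequence carries the two-base code
that is exactly the union of the parental bases (G+T -> K, C+A -> M).

Because absolute alignment column numbers are an artifact of whichever
master alignment produced them, every diagnostic rule is anchored by a
10-nt ungapped 5' context string from a named reference haplotype; the
nominal positions are kept as metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

from .msa import GAP, Alignment, map_position
from .seqio import (
    AMBIGUITY_CODE,
    IUPAC_SETS,
    SampleTable,
    SeqRecord,
    normalize_species_label,
)

# canonical taxon names
VAGINATA = "S. vaginata"
PECTINATA_A = "S. pectinata type A"
PECTINATA_B = "S. pectinata type B"
MACROCARPA = "S. macrocarpa"
CHAKASSIENSIS = "S. chakassiensis"
HYBRID_B_MACROCARPA = "hybrid(S. pectinata type B x S. macrocarpa)"
UNRESOLVED = "unresolved"

TAXA = (VAGINATA, PECTINATA_A, PECTINATA_B, MACROCARPA, CHAKASSIENSIS)

# rule stages, in decision order
STAGE_VAGINATA = "vaginata_marker"
STAGE_AB = "ab_marker"
STAGE_DINUC_1 = "dinucleotide_1"
STAGE_DINUC_2 = "dinucleotide_2"
STAGE_SUBGROUP = "subgroup_marker"


class KeyAnchorError(ValueError):
    """A rule's anchor is absent from, or repeated in, the reference row."""


@dataclass
class DiffEvent:
    """A maximal substitution run or indel between two alignment rows."""

    kind: str  # substitution | insertion | deletion
    column: int  # 1-based alignment start column
    length: int
    states: Tuple[str, str]  # (row-a run, row-b run), gaps as '-'


@dataclass
class Rule:
    """One context-anchored diagnostic position.

    ``anchor`` is a 10-nt ungapped string occurring exactly once in the
    designated reference haplotype; the target sits ``offset`` residues
    after the anchor's end.  ``expected`` maps taxon name to the single
    IUPAC base expected there; ``hybrid_pair`` (unordered) gives the two
    parental bases whose union marks a hybrid at this position.
    """

    name: str
    stage: str
    anchor: str
    offset: int
    expected: Dict[str, str]
    hybrid_pair: Optional[Tuple[str, str]] = None
    nominal_position: Optional[int] = None

    def additive_code(self) -> Optional[str]:
        if self.hybrid_pair is None:
            return None
        pair = frozenset(self.hybrid_pair)
        if len(pair) != 2:
            raise ValueError(f"rule {self.name!r}: hybrid pair must hold 2 bases")
        return AMBIGUITY_CODE[pair]


@dataclass
class DiagnosticKey:
    """Diagnostic positions + motif-count expectations for the species key."""

    reference_id: str
    rules: List[Rule]
    references: Dict[str, str]  # haplotype id -> ungapped sequence
    reference_taxa: Dict[str, str]  # haplotype id -> taxon name
    motif: str = "GCGC"
    motif_expected: Dict[str, int] = field(default_factory=dict)
    hybrid_parents: Tuple[str, str] = (PECTINATA_B, MACROCARPA)
    nominal_positions: Dict[str, int] = field(default_factory=dict)

    def rules_for(self, stage: str) -> List[Rule]:
        return [r for r in self.rules if r.stage == stage]

    def reference_records(self) -> List[SeqRecord]:
        return [SeqRecord(id=i, residues=s) for i, s in self.references.items()]

    def to_yaml(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        doc = {
            "reference_id": self.reference_id,
            "motif": self.motif,
            "motif_expected": dict(self.motif_expected),
            "hybrid_parents": list(self.hybrid_parents),
            "nominal_positions": dict(self.nominal_positions),
            "references": dict(self.references),
            "reference_taxa": dict(self.reference_taxa),
            "rules": [
                {**asdict(r), "hybrid_pair": list(r.hybrid_pair) if r.hybrid_pair else None}
                for r in self.rules
            ],
        }
        path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
        return path

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "DiagnosticKey":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        rules = [
            Rule(
                name=r["name"],
                stage=r["stage"],
                anchor=r["anchor"],
                offset=int(r["offset"]),
                expected={k: str(v) for k, v in r["expected"].items()},
                hybrid_pair=tuple(r["hybrid_pair"]) if r.get("hybrid_pair") else None,
                nominal_position=r.get("nominal_position"),
            )
            for r in doc["rules"]
        ]
        return cls(
            reference_id=doc["reference_id"],
            rules=rules,
            references={k: str(v) for k, v in doc["references"].items()},
            reference_taxa={k: str(v) for k, v in doc.get("reference_taxa", {}).items()},
            motif=doc.get("motif", "GCGC"),
            motif_expected={k: int(v) for k, v in doc.get("motif_expected", {}).items()},
            hybrid_parents=tuple(doc.get("hybrid_parents", (PECTINATA_B, MACROCARPA))),
            nominal_positions={k: int(v) for k, v in doc.get("nominal_positions", {}).items()},
        )


@dataclass
class SpeciesCall:
    """Taxon assignment for one sample, with an evidence trail."""

    sample_id: str
    call: str
    evidence: List[Tuple[str, str, str]]  # (rule name, observed, matched taxon)
    conflicts: List[str]
    ambiguity_fraction: float


@dataclass
class AmbiguityProfile:
    fraction: float
    positions: List[int]  # 1-based ungapped positions of ambiguous residues
    flagged: bool


# --------------------------------------------------------------------------
# pairwise difference profiling


def extract_diff_events(aln: Alignment) -> List[DiffEvent]:
    """Maximal substitution/indel runs between the two rows of ``aln``.

    Insertion means the first row has the gap (material present only in
    the second row); deletion the reverse.  Columns gapped in both rows
    are neutral and break runs.
    """
    if aln.nrows != 2:
        raise ValueError("extract_diff_events needs exactly 2 rows")
    ra, rb = aln.rows
    events: List[DiffEvent] = []
    cur: Optional[DiffEvent] = None
    for k in range(aln.length):
        ca, cb = ra[k], rb[k]
        if ca == GAP and cb == GAP:
            kind = None
        elif ca == GAP:
            kind = "insertion"
        elif cb == GAP:
            kind = "deletion"
        elif ca != cb:
            kind = "substitution"
        else:
            kind = None
        if kind is None:
            cur = None
            continue
        if cur is not None and cur.kind == kind and cur.column + cur.length == k + 1:
            cur.length += 1
            cur.states = (cur.states[0] + ca, cur.states[1] + cb)
        else:
            cur = DiffEvent(kind=kind, column=k + 1, length=1, states=(ca, cb))
            events.append(cur)
    return events


def apply_diff_events(aln: Alignment, events: Sequence[DiffEvent]) -> str:
    """Replay events onto row 1 of ``aln``; returns the reconstructed
    (ungapped) row 2.  Used as the round-trip check on event extraction."""
    chars = list(aln.rows[0])
    for ev in events:
        for k in range(ev.length):
            chars[ev.column - 1 + k] = ev.states[1][k]
    return "".join(chars).replace(GAP, "")


def event_inventory(events: Sequence[DiffEvent]) -> Dict[Tuple[str, int], int]:
    """Multiset of (kind, length) pairs, e.g. {("substitution", 1): 16, ...}."""
    out: Dict[Tuple[str, int], int] = {}
    for ev in events:
        key = (ev.kind, ev.length)
        out[key] = out.get(key, 0) + 1
    return out


# --------------------------------------------------------------------------
# motif counting (in-silico restriction-site assay)


def count_motif(seq: Union[SeqRecord, str], motif: str, mode: str = "strict") -> int:
    """Count occurrences of ``motif`` in the ungapped sequence.

    Overlapping occurrences count.  ``strict`` requires exact characters;
    ``compatible`` counts windows where every residue's IUPAC base set
    contains the motif base (so S matches G or C, etc.).
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = motif.upper()
    if any(b not in "ACGT" for b in motif):
        raise ValueError("motif must be unambiguous A/C/G/T")
    s = (seq.residues if isinstance(seq, SeqRecord) else seq).upper().replace(GAP, "")
    k = len(motif)
    n = 0
    if mode == "strict":
        for i in range(len(s) - k + 1):
            if s[i:i + k] == motif:
                n += 1
    elif mode == "compatible":
        for i in range(len(s) - k + 1):
            window = s[i:i + k]
            if all(motif[j] in IUPAC_SETS[window[j]] for j in range(k)):
                n += 1
    else:
        raise ValueError("mode must be 'strict' or 'compatible'")
    return n


# --------------------------------------------------------------------------
# key anchoring and classification


def locate_rule(aln: Alignment, rule: Rule, reference_id: str) -> int:
    """Alignment column (1-based) the rule points at, via the reference row."""
    ref = aln.degapped(reference_id)
    hits = ref.count(rule.anchor)
    if hits == 0:
        raise KeyAnchorError(
            f"rule {rule.name!r}: anchor {rule.anchor!r} absent from "
            f"reference {reference_id!r}"
        )
    if hits > 1:
        raise KeyAnchorError(
            f"rule {rule.name!r}: anchor {rule.anchor!r} occurs {hits} times "
            f"in reference {reference_id!r}"
        )
    start = ref.find(rule.anchor)
    target = start + len(rule.anchor) + rule.offset  # 1-based residue index
    return map_position(aln, reference_id, target)


def ambiguity_profile(
    seq: Union[SeqRecord, str], threshold: float = 0.005
) -> AmbiguityProfile:
    """Fraction and 1-based positions of non-A/C/G/T residues (ungapped).

    Samples above ``threshold`` are flagged "polymorphic" -- the signature
    of a consensus built over superimposed chromatogram peaks at many
    sites (intra-individual polymorphism), as opposed to the two-site
    additivity of a clean hybrid.
    """
    s = (seq.residues if isinstance(seq, SeqRecord) else seq).upper().replace(GAP, "")
    positions = [k + 1 for k, c in enumerate(s) if c not in "ACGT"]
    fraction = len(positions) / len(s) if s else 0.0
    return AmbiguityProfile(fraction, positions, fraction > threshold)


def _informative(rules: Sequence[Rule], obs: Dict[str, str]):
    return [(r, obs[r.name]) for r in rules if obs[r.name] != GAP]


def classify_sample(
    sample_id: str,
    aln: Alignment,
    key: DiagnosticKey,
    polymorphic_threshold: float = 0.005,
) -> SpeciesCall:
    """Assign a sample row of ``aln`` to a taxon using the diagnostic key.

    Decision order: (1) the vaginata/pectinata separator states, with the
    strict motif (CfoI site) count as corroboration; (2) the type A/B
    separator states; (3) the diagnostic dinucleotide: type-B state leads
    to the subgroup (position-524) rule deciding type B vs.
    *S. chakassiensis*; macrocarpa state calls *S. macrocarpa*; the exact
    additivity pattern at BOTH positions calls a hybrid.  Anything else is
    unresolved, with partial evidence and conflicts recorded.  Gaps at
    diagnostic positions make a rule uninformative; they never block a
    call on the remaining rules.
    """
    row = aln.row(sample_id)
    seq = aln.degapped(sample_id)
    cols = {r.name: locate_rule(aln, r, key.reference_id) for r in key.rules}
    obs = {name: row[col - 1] for name, col in cols.items()}
    strict_count = count_motif(seq, key.motif, "strict")
    prof = ambiguity_profile(seq, polymorphic_threshold)

    evidence: List[Tuple[str, str, str]] = []
    conflicts: List[str] = []

    def check_motif(taxon: str) -> None:
        exp = key.motif_expected.get(taxon)
        if exp is None:
            return
        if strict_count == exp:
            evidence.append((f"motif:{key.motif}", str(strict_count), taxon))
        else:
            conflicts.append(
                f"strict {key.motif} count {strict_count} != {exp} "
                f"expected for {taxon}"
            )

    def call(taxon: str) -> SpeciesCall:
        return SpeciesCall(sample_id, taxon, evidence, conflicts, prof.fraction)

    # stage 1: vaginata vs the pectinata lineage
    vag_rules = key.rules_for(STAGE_VAGINATA)
    inf = _informative(vag_rules, obs)
    if inf:
        vag_hits = [o == r.expected[VAGINATA] for r, o in inf]
        pect_hits = [o == r.expected[PECTINATA_B] for r, o in inf]
        if all(vag_hits):
            for r, o in inf:
                evidence.append((r.name, o, VAGINATA))
            check_motif(VAGINATA)
            return call(VAGINATA)
        if any(vag_hits):
            conflicts.append("mixed states at vaginata/pectinata separator positions")
        for (r, o), hit in zip(inf, pect_hits):
            if hit:
                evidence.append((r.name, o, "pectinata lineage"))

    # stage 2: type A vs type B lineage
    ab_rules = key.rules_for(STAGE_AB)
    inf = _informative(ab_rules, obs)
    if inf:
        a_hits = [o == r.expected[PECTINATA_A] for r, o in inf]
        b_hits = [o == r.expected[PECTINATA_B] for r, o in inf]
        if all(a_hits):
            for r, o in inf:
                evidence.append((r.name, o, PECTINATA_A))
            check_motif(PECTINATA_A)
            return call(PECTINATA_A)
        if any(a_hits):
            conflicts.append("mixed states at type A/type B separator positions")
        for (r, o), hit in zip(inf, b_hits):
            if hit:
                evidence.append((r.name, o, "type B lineage"))

    # stage 3: the diagnostic dinucleotide and the subgroup marker
    try:
        (r1,) = key.rules_for(STAGE_DINUC_1)
        (r2,) = key.rules_for(STAGE_DINUC_2)
        (r5,) = key.rules_for(STAGE_SUBGROUP)
    except ValueError as exc:
        raise ValueError(
            "key must define exactly one rule per dinucleotide/subgroup stage"
        ) from exc
    o1, o2, o5 = obs[r1.name], obs[r2.name], obs[r5.name]
    parent_b, parent_m = key.hybrid_parents
    add1, add2 = r1.additive_code(), r2.additive_code()

    def subgroup_check(taxon: str) -> None:
        exp = r5.expected.get(taxon)
        if exp is not None and o5 != GAP and o5 != exp:
            conflicts.append(
                f"{r5.name}: observed {o5!r}, expected {exp!r} for {taxon}"
            )

    if o1 == r1.expected[parent_b] and o2 == r2.expected[parent_b]:
        evidence.append((r1.name, o1, parent_b))
        evidence.append((r2.name, o2, parent_b))
        if o5 == r5.expected[CHAKASSIENSIS]:
            evidence.append((r5.name, o5, CHAKASSIENSIS))
            check_motif(CHAKASSIENSIS)
            return call(CHAKASSIENSIS)
        if o5 == r5.expected[PECTINATA_B]:
            evidence.append((r5.name, o5, PECTINATA_B))
            check_motif(PECTINATA_B)
            return call(PECTINATA_B)
        conflicts.append(
            f"{r5.name}: state {o5!r} resolves neither {PECTINATA_B} "
            f"nor {CHAKASSIENSIS}"
        )
        return call(UNRESOLVED)
    if o1 == r1.expected[parent_m] and o2 == r2.expected[parent_m]:
        evidence.append((r1.name, o1, parent_m))
        evidence.append((r2.name, o2, parent_m))
        subgroup_check(MACROCARPA)
        check_motif(MACROCARPA)
        return call(MACROCARPA)
    if o1 == add1 and o2 == add2:
        hybrid = f"hybrid({parent_b} x {parent_m})"
        evidence.append((r1.name, o1, hybrid))
        evidence.append((r2.name, o2, hybrid))
        subgroup_check(PECTINATA_B)
        check_motif(PECTINATA_B)
        return call(hybrid)
    if (o1 == add1) != (o2 == add2):
        conflicts.append(
            "partial hybrid signal: additivity at only one of the two "
            "diagnostic dinucleotide positions"
        )
        return call(UNRESOLVED)
    conflicts.append(
        f"dinucleotide states ({o1!r}, {o2!r}) match no taxon in the key"
    )
    return call(UNRESOLVED)


# --------------------------------------------------------------------------
# grouping and discordance


GROUP_OF = {
    VAGINATA: "I",
    PECTINATA_A: "II",
    PECTINATA_B: "III-I",
    MACROCARPA: "III-I",
    HYBRID_B_MACROCARPA: "III-I",
    CHAKASSIENSIS: "III-II",
}


def partition_groups(
    calls: Sequence[SpeciesCall],
) -> Tuple[Dict[str, str], List[str]]:
    """Partition calls into tree groups I / II / III-I / III-II.

    Group I holds *S. vaginata*; II the type-A samples; III-I type B,
    *S. macrocarpa* and their hybrids; III-II *S. chakassiensis*.
    Unresolved samples are returned separately, never silently dropped.
    """
    groups: Dict[str, str] = {}
    unresolved: List[str] = []
    for c in calls:
        taxon = c.call
        if taxon.startswith("hybrid("):
            taxon = HYBRID_B_MACROCARPA
        if taxon in GROUP_OF:
            groups[c.sample_id] = GROUP_OF[taxon]
        else:
            unresolved.append(c.sample_id)
    return groups, unresolved


_CALL_EPITHETS = {
    VAGINATA: {"vaginata"},
    PECTINATA_A: {"pectinata"},
    PECTINATA_B: {"pectinata"},
    MACROCARPA: {"macrocarpa"},
    CHAKASSIENSIS: {"chakassiensis"},
}


def _epithets_for_call(call: str) -> set:
    if call.startswith("hybrid("):
        inner = call[len("hybrid("):-1]
        parts = [p.strip() for p in inner.split(" x ")]
        out = set()
        for p in parts:
            out |= _CALL_EPITHETS.get(p, set())
        return out
    return _CALL_EPITHETS.get(call, set())


def _epithet(label: str) -> Optional[str]:
    norm = normalize_species_label(label)
    if norm == "unknown":
        return None
    tokens = norm.split()
    return tokens[1] if len(tokens) >= 2 and tokens[0] == "S." else norm


def discordance_report(
    calls: Sequence[SpeciesCall],
    metadata: SampleTable,
) -> Tuple[pd.DataFrame, List[str]]:
    """Morphology/molecule concordance, one row per called sample.

    Species matching works at the epithet level with *Stuckenia* and
    *Potamogeton* binomials treated as synonymous; a morphology label of
    "S. pectinata" is concordant with either molecular type, and a hybrid
    call is concordant with either parent's morphology label.  Metadata
    rows with no sequenced sample are returned as orphans.
    """
    rows = []
    called_ids = set()
    for c in calls:
        called_ids.add(c.sample_id)
        label = metadata.label_for(c.sample_id)
        note = ""
        if label is None:
            label = "unknown"
            note = "no metadata row"
        morph_ep = _epithet(label)
        call_eps = _epithets_for_call(c.call)
        if c.call == UNRESOLVED:
            concordant = False
            note = note or "molecular call unresolved"
        elif morph_ep is None:
            concordant = False
            note = note or "morphology label not comparable"
        else:
            concordant = morph_ep in call_eps
        rows.append(
            {
                "sample_id": c.sample_id,
                "morphology_label": label,
                "molecular_call": c.call,
                "concordant": concordant,
                "note": note,
            }
        )
    orphans = [s for s in metadata.sample_ids if s not in called_ids]
    return pd.DataFrame(rows), orphans
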