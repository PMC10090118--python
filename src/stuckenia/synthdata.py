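"""Seeded synthetic haplotype panels with the locus's difference structure.

The generator builds five spacer haplotypes whose pairwise differences
reproduce, exactly and by construction, the difference inventory that
separates the five taxa at this locus:

* *S. vaginata* vs. either *S. pectinata* type: 3 indels (1, 1 and 9 nt,
  carried as insertions in the vaginata haplotype) plus 16 one-nt and
  2 two-nt substitution runs, all at columns where types A and B agree;
* type A vs. type B: 5 one-nt and 1 two-nt substitution runs, no indels;
* *S. macrocarpa*: type B with a 2-nt state change at the diagnostic
  dinucleotide (nominal positions 102-103: G,C -> T,A);
* *S. chakassiensis*: type B with one change at the nominal position 524
  (T -> C; which allele marks the species is a key parameter, and this
  assignment is an explicit, documented choice of the shipped key);
* strict GCGC (CfoI site) counts 2/2/2/2 for the pectinata-lineage
  haplotypes and 1 for vaginata -- one of vaginata's 16 substitutions is
  constrained to hit the third base of the second planted motif.

Edit events never overlap, never sit adjacent (which would merge runs),
and never hit diagnostic positions, so measured difference profiles equal
the designed ones.  Everything is deterministic per seed; constraint
violations (e.g. an edit accidentally creating a new GCGC) trigger a
bounded retry with fresh draws.

Hybrid samples are the position-wise IUPAC union of the two parent
haplotypes; simulated sample sets default to a 28-sample composition
mirroring a field study of this genus, including its morphology
misidentification pattern and one multiply-polymorphic sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .genotyping import (
    CHAKASSIENSIS,
    HYBRID_B_MACROCARPA,
    MACROCARPA,
    PECTINATA_A,
    PECTINATA_B,
    STAGE_AB,
    STAGE_DINUC_1,
    STAGE_DINUC_2,
    STAGE_SUBGROUP,
    STAGE_VAGINATA,
    VAGINATA,
    DiagnosticKey,
    Rule,
    count_motif,
)
from .seqio import AMBIGUITY_CODE, SeqRecord, write_fasta

REF_IDS = {
    VAGINATA: "ref_vaginata",
    PECTINATA_A: "ref_pectinata_A",
    PECTINATA_B: "ref_pectinata_B",
    MACROCARPA: "ref_macrocarpa",
    CHAKASSIENSIS: "ref_chakassiensis",
}

#: 28-sample study-mirror composition (counts of true taxa).
STUDY_COMPOSITION = {
    VAGINATA: 2,
    PECTINATA_A: 2,
    PECTINATA_B: 7,
    MACROCARPA: 8,
    CHAKASSIENSIS: 6,
    "hybrid": 3,
}

# morphology labels per true taxon recreating the study's misidentification
# pattern (morphology totals 7/7/9/5 across pectinata/vaginata/macrocarpa/
# chakassiensis; 6 samples discordant with their molecular call)
_STUDY_MORPHOLOGY = {
    VAGINATA: ["S. vaginata", "S. vaginata"],
    PECTINATA_A: ["S. pectinata", "S. pectinata"],
    PECTINATA_B: ["S. vaginata"] * 4 + ["S. pectinata"] * 3,
    MACROCARPA: ["S. macrocarpa"] * 7 + ["S. pectinata"],
    "hybrid": ["S. macrocarpa", "S. macrocarpa", "S. pectinata"],
    CHAKASSIENSIS: ["S. chakassiensis"] * 5 + ["S. vaginata"],
}

_BASES = np.array(list("ACGT"))


class GenerationError(RuntimeError):
    """Constraint satisfaction failed after the bounded number of retries."""


class _Retry(Exception):
    def __init__(self, constraint: str):
        self.constraint = constraint


@dataclass(frozen=True)
class PanelConfig:
    """Tunable geometry of the synthetic panel (1-based base coordinates)."""

    length: int = 700
    dinuc_position: Tuple[int, int] = (102, 103)
    subgroup_position: int = 524
    motif: str = "GCGC"
    motif_positions: Tuple[int, int] = (150, 400)  # starts of the two sites
    dinuc_states_b: Tuple[str, str] = ("G", "C")
    dinuc_states_macrocarpa: Tuple[str, str] = ("T", "A")
    subgroup_state_b: str = "T"
    subgroup_state_chakassiensis: str = "C"
    n_vaginata_singles: int = 16
    n_vaginata_doubles: int = 2
    n_ab_singles: int = 5
    n_ab_doubles: int = 1
    indel_lengths: Tuple[int, ...] = (1, 1, 9)
    indel_clearance: int = 20
    anchor_length: int = 10
    max_tries: int = 200

    def __post_init__(self) -> None:
        if self.length < 600:
            raise ValueError("panel length must be >= 600")


@dataclass
class HaplotypePanel:
    """The five reference haplotypes plus full edit bookkeeping."""

    seed: int
    config: PanelConfig
    base: str  # = pectinata type A sequence
    haplotypes: Dict[str, str]  # taxon -> ungapped sequence
    vaginata_subs: List[Tuple[int, int]]  # (1-based start, length), base coords
    ab_subs: List[Tuple[int, int]]
    insertions: List[Tuple[int, int, str]]  # (after 1-based base pos, len, seg)
    key: DiagnosticKey = field(repr=False, default=None)

    def records(self) -> List[SeqRecord]:
        return [
            SeqRecord(id=REF_IDS[t], residues=self.haplotypes[t])
            for t in (VAGINATA, PECTINATA_A, PECTINATA_B, MACROCARPA, CHAKASSIENSIS)
        ]

    def base_to_vaginata(self, pos: int) -> int:
        """Map a 1-based base-coordinate position into vaginata coordinates."""
        shift = sum(ln for after, ln, _ in self.insertions if after < pos)
        return pos + shift

    def hybrid_sequence(self) -> str:
        """Position-wise IUPAC union of type B and macrocarpa haplotypes."""
        b = self.haplotypes[PECTINATA_B]
        m = self.haplotypes[MACROCARPA]
        out = []
        for cb, cm in zip(b, m):
            if cb == cm:
                out.append(cb)
            else:
                out.append(AMBIGUITY_CODE[frozenset({cb, cm})])
        return "".join(out)

    def protected_positions(self, taxon: str) -> frozenset:
        """1-based positions (in the taxon's own coordinates) that noise
        must not touch: all diagnostic rule targets and both motif spans."""
        cfg = self.config
        base_prot = set()
        for r in self.key.rules:
            base_prot.add(r.nominal_position)
        for start in cfg.motif_positions:
            base_prot.update(range(start, start + len(cfg.motif)))
        if taxon == VAGINATA:
            return frozenset(self.base_to_vaginata(p) for p in base_prot)
        return frozenset(base_prot)


def _strict_positions(s: str, motif: str) -> List[int]:
    k = len(motif)
    return [i for i in range(len(s) - k + 1) if s[i:i + k] == motif]


def _sample_runs(rng, free: np.ndarray, lengths: Sequence[int], tries: int = 400):
    """Place runs of the given lengths on free 0-based positions, keeping
    one spare position on each side so no two events touch."""
    placed = []
    free = free.copy()
    for ln in lengths:
        ok = False
        for _ in range(tries):
            start = int(rng.integers(0, len(free) - ln))
            lo, hi = max(0, start - 1), min(len(free), start + ln + 1)
            if free[lo:hi].all():
                free[lo:hi] = False
                placed.append((start, ln))
                ok = True
                break
        if not ok:
            raise _Retry(f"could not place a length-{ln} event")
    return placed, free


def _mutate(rng, old: str) -> str:
    choices = [b for b in "ACGT" if b != old]
    return choices[int(rng.integers(0, 3))]


def _apply_subs(seq: List[str], runs: List[Tuple[int, int]], rng) -> None:
    for start, ln in runs:  # 0-based starts here
        for k in range(ln):
            seq[start + k] = _mutate(rng, seq[start + k])


def _build_attempt(rng: np.random.Generator, cfg: PanelConfig) -> HaplotypePanel:
    L = cfg.length
    motif = cfg.motif
    base = list(_BASES[rng.integers(0, 4, size=L)])

    # plant the two restriction-site motifs and the diagnostic states
    for start in cfg.motif_positions:
        base[start - 1:start - 1 + len(motif)] = list(motif)
    d1, d2 = cfg.dinuc_position
    base[d1 - 1], base[d2 - 1] = cfg.dinuc_states_b
    base[cfg.subgroup_position - 1] = cfg.subgroup_state_b

    planted = {p - 1 for p in cfg.motif_positions}
    protected = set()
    for start in cfg.motif_positions:
        protected.update(range(start - 1, start - 1 + len(motif)))
    diag = {d1 - 1, d2 - 1, cfg.subgroup_position - 1}
    protected |= diag

    # scrub accidental strict motif occurrences from the base sequence
    for _ in range(30):
        extras = [p for p in _strict_positions("".join(base), motif) if p not in planted]
        if not extras:
            break
        for p in extras:
            editable = [q for q in range(p, p + len(motif)) if q not in protected]
            if not editable:
                raise _Retry("accidental motif overlaps protected positions")
            q = editable[int(rng.integers(0, len(editable)))]
            base[q] = _mutate(rng, base[q])
    else:
        raise _Retry("could not scrub accidental motifs")
    base_s = "".join(base)
    if count_motif(base_s, motif, "strict") != 2:
        raise _Retry("base motif count != 2 after scrub")

    # eligibility mask for substitution events (0-based), with margins
    free = np.ones(L, dtype=bool)
    for p in protected:
        lo, hi = max(0, p - 2), min(L, p + 3)
        free[lo:hi] = False
    free[:cfg.anchor_length + 2] = False  # room for 10-nt 5' anchors
    free[L - 3:] = False

    ab_runs0, free = _sample_runs(
        rng, free, [2] * cfg.n_ab_doubles + [1] * cfg.n_ab_singles
    )
    forced = cfg.motif_positions[1] - 1 + 2  # third base of motif #2, 0-based
    vag_runs0, free = _sample_runs(
        rng, free, [2] * cfg.n_vaginata_doubles + [1] * (cfg.n_vaginata_singles - 1)
    )
    vag_runs0.append((forced, 1))

    # insertion slots: 'after position p' (1-based p in 0..L), far from
    # diagnostics/motifs and clear of every substitution event
    slot_free = np.ones(L + 1, dtype=bool)
    for p in protected:
        lo = max(0, p + 1 - cfg.indel_clearance)
        hi = min(L + 1, p + 1 + cfg.indel_clearance)
        slot_free[lo:hi] = False
    for start, ln in ab_runs0 + vag_runs0:
        lo, hi = max(0, start - 1), min(L + 1, start + ln + 2)
        slot_free[lo:hi] = False
    slot_free[:cfg.anchor_length + 2] = False
    slot_free[L - 2:] = False
    slots = []
    taken = slot_free.copy()
    for ln in cfg.indel_lengths:
        ok = False
        for _ in range(400):
            p = int(rng.integers(0, L + 1))
            lo, hi = max(0, p - 2), min(L + 1, p + 3)
            if taken[lo:hi].all():
                taken[lo:hi] = False
                slots.append(p)
                ok = True
                break
        if not ok:
            raise _Retry(f"could not place a length-{ln} insertion")
    insertions = []
    for p, ln in zip(slots, cfg.indel_lengths):
        seg = "".join(_BASES[rng.integers(0, 4, size=ln)])
        insertions.append((p, ln, seg))
    insertions.sort()

    # build the five haplotypes
    hap_a = list(base_s)

    hap_b = list(base_s)
    _apply_subs(hap_b, ab_runs0, rng)

    hap_mac = hap_b.copy()
    hap_mac[d1 - 1], hap_mac[d2 - 1] = cfg.dinuc_states_macrocarpa

    hap_chak = hap_b.copy()
    hap_chak[cfg.subgroup_position - 1] = cfg.subgroup_state_chakassiensis

    hap_vag = list(base_s)
    _apply_subs(hap_vag, [r for r in vag_runs0 if r[0] != forced], rng)
    # the forced substitution destroys the second motif in vaginata
    hap_vag[forced] = "A" if rng.integers(0, 2) == 0 else "T"
    for p, ln, seg in sorted(insertions, reverse=True):
        hap_vag[p:p] = list(seg)

    haps = {
        VAGINATA: "".join(hap_vag),
        PECTINATA_A: "".join(hap_a),
        PECTINATA_B: "".join(hap_b),
        MACROCARPA: "".join(hap_mac),
        CHAKASSIENSIS: "".join(hap_chak),
    }

    # verify the restriction-site contrast
    for taxon, expected in [
        (PECTINATA_A, 2), (PECTINATA_B, 2), (MACROCARPA, 2),
        (CHAKASSIENSIS, 2), (VAGINATA, 1),
    ]:
        got = count_motif(haps[taxon], motif, "strict")
        if got != expected:
            raise _Retry(f"{taxon}: strict motif count {got} != {expected}")

    panel = HaplotypePanel(
        seed=-1,  # filled by caller
        config=cfg,
        base=base_s,
        haplotypes=haps,
        vaginata_subs=sorted((s + 1, ln) for s, ln in vag_runs0),
        ab_subs=sorted((s + 1, ln) for s, ln in ab_runs0),
        insertions=insertions,
    )
    panel.key = _build_key(panel)
    return panel


def _anchor_at(ref: str, pos1: int, n: int) -> str:
    """n-nt ungapped context immediately 5' of 1-based position pos1."""
    return ref[pos1 - 1 - n:pos1 - 1]


def _build_key(panel: HaplotypePanel) -> DiagnosticKey:
    cfg = panel.config
    ref = panel.haplotypes[PECTINATA_B]
    n = cfg.anchor_length

    def make_rule(name, stage, pos1, expected, hybrid_pair=None) -> Rule:
        anchor = _anchor_at(ref, pos1, n)
        if len(anchor) != n or ref.count(anchor) != 1:
            raise _Retry(f"anchor for {name} at position {pos1} not unique")
        return Rule(
            name=name, stage=stage, anchor=anchor, offset=1,
            expected=expected, hybrid_pair=hybrid_pair, nominal_position=pos1,
        )

    d1, d2 = cfg.dinuc_position
    b1, b2 = cfg.dinuc_states_b
    m1, m2 = cfg.dinuc_states_macrocarpa
    base = panel.base
    rules = []

    # three vaginata/pectinata separator positions, from the single-nt runs
    vag_singles = [p for p, ln in panel.vaginata_subs if ln == 1]
    picked = 0
    for p in vag_singles:
        if picked == 3:
            break
        if p <= n:
            continue
        vag_state = panel.haplotypes[VAGINATA][panel.base_to_vaginata(p) - 1]
        expected = {t: base[p - 1] for t in REF_IDS}
        expected[VAGINATA] = vag_state
        try:
            rules.append(
                make_rule(f"vag_marker_{picked + 1}", STAGE_VAGINATA, p, expected)
            )
            picked += 1
        except _Retry:
            continue
    if picked < 3:
        raise _Retry("fewer than 3 usable vaginata marker anchors")

    # two type A/B separator positions, from the single-nt A/B runs
    ab_singles = [p for p, ln in panel.ab_subs if ln == 1]
    picked = 0
    for p in ab_singles:
        if picked == 2:
            break
        if p <= n:
            continue
        expected = {t: ref[p - 1] for t in REF_IDS}
        expected[PECTINATA_A] = base[p - 1]
        expected[VAGINATA] = base[p - 1]  # vaginata keeps the type-A state
        try:
            rules.append(make_rule(f"ab_marker_{picked + 1}", STAGE_AB, p, expected))
            picked += 1
        except _Retry:
            continue
    if picked < 2:
        raise _Retry("fewer than 2 usable A/B marker anchors")

    lineage_b = {PECTINATA_B: b1, MACROCARPA: m1, CHAKASSIENSIS: b1}
    rules.append(
        make_rule("dinucleotide_102", STAGE_DINUC_1, d1, lineage_b, (b1, m1))
    )
    rules.append(
        make_rule(
            "dinucleotide_103", STAGE_DINUC_2, d2,
            {PECTINATA_B: b2, MACROCARPA: m2, CHAKASSIENSIS: b2}, (b2, m2),
        )
    )
    rules.append(
        make_rule(
            "subgroup_524", STAGE_SUBGROUP, cfg.subgroup_position,
            {
                PECTINATA_B: cfg.subgroup_state_b,
                MACROCARPA: cfg.subgroup_state_b,
                CHAKASSIENSIS: cfg.subgroup_state_chakassiensis,
            },
        )
    )

    return DiagnosticKey(
        reference_id=REF_IDS[PECTINATA_B],
        rules=rules,
        references={REF_IDS[t]: panel.haplotypes[t] for t in REF_IDS},
        reference_taxa={rid: t for t, rid in REF_IDS.items()},
        motif=cfg.motif,
        motif_expected={
            VAGINATA: 1, PECTINATA_A: 2, PECTINATA_B: 2,
            MACROCARPA: 2, CHAKASSIENSIS: 2,
        },
        hybrid_parents=(PECTINATA_B, MACROCARPA),
        nominal_positions={
            "dinucleotide_102": d1,
            "dinucleotide_103": d2,
            "subgroup_524": cfg.subgroup_position,
        },
    )


def build_haplotype_panel(
    seed: int, config: Optional[PanelConfig] = None
) -> HaplotypePanel:
    """Build a constraint-checked haplotype panel, deterministic per seed."""
    cfg = config or PanelConfig()
    rng = np.random.default_rng(seed)
    last = "unknown"
    for _ in range(cfg.max_tries):
        try:
            panel = _build_attempt(rng, cfg)
            panel.seed = seed
            return panel
        except _Retry as exc:
            last = exc.constraint
    raise GenerationError(
        f"panel generation failed after {cfg.max_tries} attempts "
        f"(last constraint: {last})"
    )


# --------------------------------------------------------------------------
# sample simulation


@dataclass
class SimulatedSample:
    id: str
    taxon: str  # true taxon (or the hybrid label)
    residues: str
    morphology_label: str
    noise_positions: List[int] = field(default_factory=list)
    ambiguity_positions: List[int] = field(default_factory=list)


def _default_morphology(taxon: str) -> str:
    if taxon in (PECTINATA_A, PECTINATA_B):
        return "S. pectinata"
    if taxon == "hybrid":
        return "S. macrocarpa"
    return taxon


def simulate_samples(
    panel: HaplotypePanel,
    composition: Optional[Dict[str, int]] = None,
    noise_rate: float = 0.0,
    ambiguity_rate: float = 0.01,
    n_polymorphic: int = 0,
    morphology: str = "truth",
    seed: int = 0,
) -> Tuple[List[SimulatedSample], pd.DataFrame]:
    """Simulate a sample set from the panel, plus its truth table.

    ``composition`` maps taxon name (or "hybrid") to a count; the default
    is the 28-sample study mirror.  ``noise_rate`` (per-site substitution
    probability, <= 0.05) models Sanger consensus miscalls; it never
    touches diagnostic or motif positions, so the generating taxon stays
    well defined.  ``n_polymorphic`` type-B samples additionally receive
    ambiguity codes at ~``ambiguity_rate`` of their sites (at least five
    sites), emulating a multiply-polymorphic individual.  With
    ``morphology="study"`` (default composition only) morphology labels
    recreate the study's misidentification pattern; with "truth" they
    match the generating taxon.
    """
    if composition is None:
        composition = dict(STUDY_COMPOSITION)
        if morphology == "study" and n_polymorphic == 0:
            n_polymorphic = 1
    if not 0 <= noise_rate <= 0.05:
        raise ValueError("noise_rate must be in [0, 0.05]")
    if not 0 <= ambiguity_rate <= 0.05:
        raise ValueError("ambiguity_rate must be in [0, 0.05]")
    if morphology not in ("truth", "study"):
        raise ValueError("morphology must be 'truth' or 'study'")
    if morphology == "study" and composition != STUDY_COMPOSITION:
        raise ValueError("morphology='study' requires the default composition")

    rng = np.random.default_rng(seed)
    order = [VAGINATA, PECTINATA_A, PECTINATA_B, MACROCARPA, "hybrid", CHAKASSIENSIS]
    samples: List[SimulatedSample] = []
    idx = 0
    polymorphic_left = n_polymorphic
    for taxon in order:
        count = composition.get(taxon, 0)
        if count < 0:
            raise ValueError("composition counts must be >= 0")
        for k in range(count):
            idx += 1
            sid = f"sample_{idx:02d}"
            if taxon == "hybrid":
                residues = panel.hybrid_sequence()
                protected = panel.protected_positions(PECTINATA_B)
                true_label = HYBRID_B_MACROCARPA
            else:
                residues = panel.haplotypes[taxon]
                protected = panel.protected_positions(taxon)
                true_label = taxon
            if morphology == "study":
                morph = _STUDY_MORPHOLOGY[taxon][k]
            else:
                morph = _default_morphology(taxon)
            chars = list(residues)
            eligible = [p for p in range(1, len(chars) + 1) if p not in protected]
            noise_positions: List[int] = []
            if noise_rate > 0:
                n_noise = rng.binomial(len(eligible), noise_rate)
                if n_noise:
                    picks = rng.choice(len(eligible), size=n_noise, replace=False)
                    for pi in picks:
                        p = eligible[int(pi)]
                        if chars[p - 1] in "ACGT":
                            chars[p - 1] = _mutate(rng, chars[p - 1])
                            noise_positions.append(p)
            ambiguity_positions: List[int] = []
            if (
                taxon == PECTINATA_B
                and polymorphic_left > 0
                and k >= count - n_polymorphic
            ):
                polymorphic_left -= 1
                n_amb = max(int(rng.binomial(len(eligible), ambiguity_rate)), 5)
                picks = rng.choice(len(eligible), size=n_amb, replace=False)
                for pi in sorted(int(x) for x in picks):
                    p = eligible[pi]
                    old = chars[p - 1]
                    if old not in "ACGT":
                        continue
                    other = _mutate(rng, old)
                    chars[p - 1] = AMBIGUITY_CODE[frozenset({old, other})]
                    ambiguity_positions.append(p)
            samples.append(
                SimulatedSample(
                    id=sid,
                    taxon=true_label,
                    residues="".join(chars),
                    morphology_label=morph,
                    noise_positions=sorted(noise_positions),
                    ambiguity_positions=ambiguity_positions,
                )
            )
    truth = pd.DataFrame(
        {
            "sample_id": [s.id for s in samples],
            "true_taxon": [s.taxon for s in samples],
            "morphology_label": [s.morphology_label for s in samples],
            "polymorphic": [bool(s.ambiguity_positions) for s in samples],
            "n_noise": [len(s.noise_positions) for s in samples],
            "n_ambiguity": [len(s.ambiguity_positions) for s in samples],
        }
    )
    return samples, truth


def simulate_study(panel: HaplotypePanel, seed: int = 0):
    """The full 28-sample study mirror: default composition, study
    morphology labels, one multiply-polymorphic type-B sample, no noise."""
    return simulate_samples(
        panel, composition=None, noise_rate=0.0, morphology="study", seed=seed
    )


def write_fixture(
    panel: HaplotypePanel,
    samples: Sequence[SimulatedSample],
    truth: pd.DataFrame,
    directory: Union[str, Path],
) -> Path:
    """Write a re-loadable fixture directory.

    Files: ``panel.fasta`` (the five reference haplotypes),
    ``samples.fasta``, ``metadata.tsv`` (sample_id, morphology_label,
    note), ``truth.tsv``, ``key.yaml``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_fasta(panel.records(), directory / "panel.fasta")
    panel.key.to_yaml(directory / "key.yaml")
    if samples:
        write_fasta(
            [SeqRecord(id=s.id, residues=s.residues) for s in samples],
            directory / "samples.fasta",
        )
        meta = pd.DataFrame(
            {
                "sample_id": [s.id for s in samples],
                "morphology_label": [s.morphology_label for s in samples],
                "note": ["synthetic sample" for _ in samples],
            }
        )
        meta.to_csv(directory / "metadata.tsv", sep="\t", index=False)
        truth.to_csv(directory / "truth.tsv", sep="\t", index=False)
    return directory
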