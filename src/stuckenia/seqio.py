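"""Reading and writing barcode sequences and sample metadata.

Sequences are nuclear ribosomal ITS1--ITS2 spacer amplicons (~600-750 nt)
stored as plain FASTA.  Residues use the 15-letter IUPAC nucleotide
alphabet; ambiguity codes are meaningful here -- in Sanger consensus
sequences they mark superimposed chromatogram peaks and are the raw signal
for hybrid detection downstream.  Sample metadata (morphology-based species
labels) travels in a TSV with a header row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

GAP = "-"

#: IUPAC nucleotide codes mapped to the base sets they denote.
IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
#: Inverse lookup: base set -> single IUPAC letter.
AMBIGUITY_CODE = {s: c for c, s in IUPAC_SETS.items()}
IUPAC_LETTERS = frozenset(IUPAC_SETS)

#: Controlled morphology vocabulary (species determinations made on the
#: plant, before sequencing).  Molecular haplotype types A/B are accepted
#: too, for round-tripping classifier output.
MORPHOLOGY_LABELS = frozenset({
    "S. vaginata",
    "S. pectinata",
    "S. pectinata type A",
    "S. pectinata type B",
    "S. macrocarpa",
    "S. chakassiensis",
    "unknown",
})

_EPITHET_FIX = {
    # Latin gender variants used interchangeably in the literature.
    "pectinatus": "pectinata",
    "vaginatus": "vaginata",
    "macrocarpus": "macrocarpa",
}
_GENUS_TOKENS = {"Stuckenia", "Potamogeton", "S.", "P."}


class ParseError(ValueError):
    """Raised for malformed FASTA input or invalid residues."""


class SchemaError(ValueError):
    """Raised when a metadata table lacks required columns."""


def normalize_species_label(label: str) -> str:
    """Normalize a species label to ``S. <epithet>[ type X]`` form.

    *Stuckenia* and *Potamogeton* binomials are treated as synonymous
    (``P. chakassiensis`` == ``S. chakassiensis``), and Latin gender
    variants of the epithet are folded together.
    """
    s = str(label).strip()
    if not s or s.lower() == "unknown" or s.lower() == "nan":
        return "unknown"
    tokens = s.split()
    if tokens[0] in _GENUS_TOKENS and len(tokens) >= 2:
        epithet = tokens[1].lower()
        epithet = _EPITHET_FIX.get(epithet, epithet)
        rest = " ".join(tokens[2:])
        return f"S. {epithet}" + (f" {rest}" if rest else "")
    return s


@dataclass
class SeqRecord:
    """One barcode sequence: id, IUPAC residues, optional morphology label."""

    id: str
    residues: str
    description: str = ""
    morphology_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        self.residues = self.residues.upper()
        if not self.residues:
            raise ParseError(f"record {self.id!r}: empty sequence")
        for k, c in enumerate(self.residues):
            if c not in IUPAC_LETTERS:
                raise ParseError(
                    f"record {self.id!r}: illegal character {c!r} "
                    f"at position {k + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SampleTable:
    """Sample metadata: one row per sample id with a morphology label.

    ``out_of_panel`` lists labels that are valid strings but fall outside
    the controlled vocabulary; they are preserved (the pipeline's purpose
    includes exposing misidentification) and only flagged.
    """

    df: pd.DataFrame
    out_of_panel: list = field(default_factory=list)

    @property
    def sample_ids(self) -> list:
        return list(self.df["sample_id"])

    def label_for(self, sample_id: str) -> Optional[str]:
        hit = self.df.loc[self.df["sample_id"] == sample_id, "morphology_label"]
        return None if hit.empty else str(hit.iloc[0])

    def covers(self, ids: Iterable[str]) -> bool:
        """True when the table's id set is a superset of ``ids``."""
        return set(ids) <= set(self.sample_ids)


def _structural_precheck(path: Path) -> None:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected FASTA header "
                    f"('>') before sequence data"
                )
            return


def parse_fasta_raw(path: Union[str, Path]) -> list:
    """Parse FASTA into ``(id, description, raw_sequence)`` tuples.

    Residues are uppercased and ``.`` gap dialect is normalized to ``-``
    (with a warning); no alphabet validation or gap stripping happens here.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _structural_precheck(path)
    out = []
    seen = set()
    with open(path, encoding="utf-8") as fh:
        for header, seq in SimpleFastaParser(fh):
            parts = header.split(None, 1)
            if not parts:
                raise ParseError(f"{path}: empty FASTA header line")
            rec_id = parts[0]
            desc = parts[1] if len(parts) > 1 else ""
            if rec_id in seen:
                raise ParseError(f"{path}: duplicate sequence id {rec_id!r}")
            seen.add(rec_id)
            seq = seq.upper()
            if "." in seq:
                warnings.warn(
                    f"{path}: record {rec_id!r}: '.' gap characters "
                    f"normalized to '-'",
                    stacklevel=2,
                )
                seq = seq.replace(".", GAP)
            if not seq:
                raise ParseError(f"{path}: record {rec_id!r}: empty sequence")
            out.append((rec_id, desc, seq))
    if not out:
        raise ParseError(f"{path}: no FASTA records found")
    return out


def read_fasta(path: Union[str, Path]) -> list:
    """Read unaligned sequences; returns :class:`SeqRecord` in file order.

    Gap characters in the input are stripped with a warning (an aligned
    file fed to the unaligned reader); use :func:`stuckenia.msa.read_alignment`
    to keep them.
    """
    records = []
    for rec_id, desc, seq in parse_fasta_raw(path):
        if GAP in seq:
            warnings.warn(
                f"record {rec_id!r}: gap characters stripped "
                f"(unaligned input mode)",
                stacklevel=2,
            )
            seq = seq.replace(GAP, "")
        records.append(SeqRecord(id=rec_id, residues=seq, description=desc))
    return records


def write_fasta(
    records: Sequence,
    path: Union[str, Path],
    wrap_width: int = 70,
    aligned: bool = False,
) -> Path:
    """Write records (``SeqRecord`` or ``(id, seq)`` pairs) as wrapped FASTA.

    ``aligned=True`` permits and preserves ``-`` gap characters.
    """
    if wrap_width < 1:
        raise ValueError("wrap_width must be positive")
    path = Path(path)
    if not records:
        warnings.warn(f"writing empty FASTA file {path}", stacklevel=2)
    allowed = IUPAC_LETTERS | ({GAP} if aligned else set())
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            if isinstance(rec, SeqRecord):
                rec_id, seq, desc = rec.id, rec.residues, rec.description
            else:
                rec_id, seq = rec[0], rec[1].upper()
                desc = rec[2] if len(rec) > 2 else ""
            bad = set(seq) - allowed
            if bad:
                raise ParseError(
                    f"record {rec_id!r}: characters {sorted(bad)} not "
                    f"writable ({'aligned' if aligned else 'unaligned'} mode)"
                )
            header = f">{rec_id}" + (f" {desc}" if desc else "")
            fh.write(header + "\n")
            for k in range(0, len(seq), wrap_width):
                fh.write(seq[k:k + wrap_width] + "\n")
    return path


def read_metadata(path: Union[str, Path]) -> SampleTable:
    """Read a sample-metadata TSV with columns sample_id, morphology_label.

    Optional columns (``accession``, ``note``) are carried through.  Labels
    outside the controlled vocabulary are kept but flagged via
    ``SampleTable.out_of_panel``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("sample_id", "morphology_label"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise SchemaError(f"{path}: duplicate sample ids {dups}")
    out_of_panel = []
    for label in df["morphology_label"]:
        norm = normalize_species_label(label)
        if norm not in MORPHOLOGY_LABELS and label not in out_of_panel:
            out_of_panel.append(label)
    if out_of_panel:
        warnings.warn(
            f"{path}: morphology labels outside the controlled vocabulary "
            f"(kept, flagged): {out_of_panel}",
            stacklevel=2,
        )
    return SampleTable(df=df, out_of_panel=out_of_panel)
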