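"""Readers and writers for all external formats.

Sequences travel as :class:`SequenceRecord`; taxon-group assignments as
:class:`TaxonomyMap`; Pfam-style domain annotations as
:class:`DomainAnnotation`.  Coordinates in domain tables are 1-based
inclusive (Pfam/GFF convention).  Unknown residues are normalised to ``X``
(protein) or ``N`` (nucleotide) rather than rejected, because EST-derived
peptides are noisy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError, FormatError
from .trees import SupportTree

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")
NUCLEOTIDE_ALPHABET = set("ACGTN")

ROLES = ("donor", "recipient", "close_relative", "other_eukaryote", "prokaryote")
REQUIRED_ROLES = ("donor", "recipient", "other_eukaryote")
NONDONOR_ROLES = ("close_relative", "other_eukaryote", "prokaryote")


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein or nucleotide sequence."""

    id: str
    seq: str
    moltype: str = "protein"  # "protein" | "nucleotide"

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"sequence {self.id!r} is empty")
        if self.moltype not in ("protein", "nucleotide"):
            raise DataError(f"unknown moltype {self.moltype!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class DomainAnnotation:
    """One conserved-domain hit on a protein, 1-based inclusive coordinates."""

    seq_id: str
    domain: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise FormatError(
                f"domain {self.domain!r} on {self.seq_id!r}: "
                f"bad coordinates {self.start}..{self.end}"
            )


class TaxonomyMap:
    """Maps sequence ids to taxonomy groups, and groups to screening roles.

    Each group owns a set of id prefixes.  An id must match exactly one
    prefix across all groups; ambiguous matches are an error.  Roles
    partition groups into donor, recipient, close_relative, other_eukaryote
    and prokaryote; donor, recipient and other_eukaryote must be non-empty
    (without at least one group outside donor+recipient, monophyly tests are
    uninformative).
    """

    def __init__(self, groups: dict, unknown_group: Optional[str] = None):
        # groups: name -> {"role": str, "patterns": [prefix, ...]}
        self.groups = dict(groups)
        self.unknown_group = unknown_group
        self._patterns = []  # (prefix, group)
        for name, info in self.groups.items():
            role = info.get("role")
            if role not in ROLES:
                raise FormatError(f"group {name!r} has unknown role {role!r}")
            for pat in info.get("patterns", []):
                self._patterns.append((str(pat), name))
        for role in REQUIRED_ROLES:
            if not self.groups_with_role(role):
                raise FormatError(f"taxonomy config defines no {role} group")
        donors = set(self.groups_with_role("donor"))
        recips = set(self.groups_with_role("recipient"))
        if donors & recips:
            raise FormatError("a group cannot be both donor and recipient")
        if unknown_group is not None and unknown_group not in self.groups:
            raise FormatError(f"unknown-id default group {unknown_group!r} undefined")

    def groups_with_role(self, role: str) -> list:
        return [g for g, info in self.groups.items() if info["role"] == role]

    def role_of(self, group: str) -> str:
        return self.groups[group]["role"]

    def resolve(self, seq_id: str) -> str:
        """Group label for a sequence id (prefix match, must be unique)."""
        hits = [(pat, grp) for pat, grp in self._patterns if seq_id.startswith(pat)]
        if len(hits) > 1:
            pats = ", ".join(repr(p) for p, _ in hits)
            raise DataError(f"id {seq_id!r} matches multiple patterns: {pats}")
        if not hits:
            if self.unknown_group is not None:
                return self.unknown_group
            raise DataError(f"id {seq_id!r} matches no taxonomy pattern")
        return hits[0][1]

    def role_of_id(self, seq_id: str) -> str:
        return self.role_of(self.resolve(seq_id))


# --------------------------------------------------------------------- FASTA


def _clean_seq(raw: str, moltype: str, rec_id: str) -> str:
    seq = raw.upper()
    if moltype == "protein":
        alphabet, unknown = PROTEIN_ALPHABET, "X"
    else:
        alphabet, unknown = NUCLEOTIDE_ALPHABET, "N"
    if set(seq) <= alphabet:
        return seq
    return "".join(c if c in alphabet else unknown for c in seq)


def read_fasta(path, moltype: str = "protein") -> List[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, enforcing unique ids."""
    path = Path(path)
    records: List[SequenceRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = _clean_seq(str(rec.seq), moltype, rec.id)
        if not seq:
            raise FormatError(f"{path}: sequence {rec.id!r} is empty")
        records.append(SequenceRecord(rec.id, seq, moltype))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, wrap: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i : i + wrap] + "\n")


# --------------------------------------------------- six-frame translation

_FRAME_TAGS = ("+1", "+2", "+3", "-1", "-2", "-3")


def translate_six_frames(record: SequenceRecord) -> List[SequenceRecord]:
    """Translate a nucleotide sequence in all six reading frames.

    Frames +1..+3 read the forward strand at offsets 0..2; frames -1..-3
    read the reverse complement likewise (transeq convention).  Stop codons
    are rendered as '*', trailing partial codons dropped.  The frame tag is
    suffixed to the id; frames too short to yield a codon give an empty
    peptide and are returned with an empty seq guarded as 'X'-free empty
    string (callers may drop them).
    """
    if record.moltype != "nucleotide":
        raise DataError(f"translate_six_frames: {record.id!r} is not nucleotide")
    fwd = Seq(record.seq)
    rev = fwd.reverse_complement()
    out = []
    for tag, strand in zip(_FRAME_TAGS, [fwd, fwd, fwd, rev, rev, rev]):
        off = int(tag[1]) - 1
        sub = strand[off : off + 3 * ((len(strand) - off) // 3)]
        pep = str(sub.translate(table=1))
        out.append(
            SequenceRecord(f"{record.id}_frame{tag}", pep, "protein")
            if pep
            else _EmptyFrame(f"{record.id}_frame{tag}")
        )
    return out


@dataclass(frozen=True)
class _EmptyFrame:
    """Placeholder for a reading frame too short to contain a codon."""

    id: str
    seq: str = ""
    moltype: str = "protein"

    def __len__(self) -> int:
        return 0


# ------------------------------------------------------------ taxonomy YAML


def read_taxonomy_config(path) -> TaxonomyMap:
    """Read a YAML taxonomy config.

    Layout::

        unknown: error            # or the name of a default group
        groups:
          algae:    {role: donor,           patterns: [alga]}
          animals:  {role: recipient,       patterns: [anim]}
          protists: {role: other_eukaryote, patterns: [euk]}
    """
    path = Path(path)
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(data, dict) or "groups" not in data:
        raise FormatError(f"{path}: expected a mapping with a 'groups' key")
    unknown = data.get("unknown", "error")
    unknown_group = None if unknown == "error" else unknown
    return TaxonomyMap(data["groups"], unknown_group=unknown_group)


def write_taxonomy_config(tax: TaxonomyMap, path) -> None:
    data = {
        "unknown": tax.unknown_group or "error",
        "groups": {
            name: {"role": info["role"], "patterns": list(info["patterns"])}
            for name, info in tax.groups.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ------------------------------------------------------------- domain table


def read_domain_table(path, sequences: Optional[dict] = None) -> List[DomainAnnotation]:
    """Read a 4-column TSV (seq_id, domain, start, end) of domain hits.

    Rows are returned grouped by sequence (first-appearance order) and
    sorted by start within each sequence.  If ``sequences`` (id -> length or
    SequenceRecord) is given, coordinates are cross-checked against lengths.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str, "domain": str})
    required = ["seq_id", "domain", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    annos: List[DomainAnnotation] = []
    for idx, row in df.iterrows():
        line = idx + 2  # 1-based, after header
        try:
            anno = DomainAnnotation(row["seq_id"], row["domain"], int(row["start"]), int(row["end"]))
        except FormatError as exc:
            raise FormatError(f"{path}: line {line}: {exc}") from exc
        if sequences is not None and anno.seq_id in sequences:
            length = sequences[anno.seq_id]
            if hasattr(length, "seq"):
                length = len(length.seq)
            if anno.end > length:
                raise FormatError(
                    f"{path}: line {line}: end {anno.end} beyond sequence "
                    f"length {length} for {anno.seq_id!r}"
                )
        annos.append(anno)
    order = {sid: i for i, sid in enumerate(dict.fromkeys(df["seq_id"]))}
    annos.sort(key=lambda a: (order[a.seq_id], a.start, a.end))
    return annos


def write_domain_table(annotations: Iterable[DomainAnnotation], path) -> None:
    rows = [(a.seq_id, a.domain, a.start, a.end) for a in annotations]
    pd.DataFrame(rows, columns=["seq_id", "domain", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


# ----------------------------------------------------------------- Newick


def read_newick(path) -> SupportTree:
    path = Path(path)
    with open(path) as fh:
        return SupportTree.from_newick(fh.read())


def write_newick(tree: SupportTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
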