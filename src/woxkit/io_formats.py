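"""Sequence, gene-model and table I/O shared by every analysis module.

Coordinates follow GFF3 conventions throughout: 1-based, inclusive on both
ends.  CDS extraction reverse-complements the concatenated coding sequence
once, so the returned record always reads 5'->3' in transcript orientation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable

__all__ = [
    "SequenceRecord",
    "GeneModel",
    "CodonTable",
    "standard_codon_table",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "extract_cds",
    "translate",
    "reverse_complement",
    "read_tsv",
]

# Alphabets accepted per declared record type (after uppercasing).  Genomic DNA
# may carry IUPAC ambiguity codes; proteins may carry X for unknown residues.
_ALPHABETS = {
    "dna": set("ACGTNRYSWKMBDHV"),
    "protein": set("ACDEFGHIKLMNPQRSTVWYX*"),
    "dna-aligned": set("ACGTNRYSWKMBDHV-"),
    "protein-aligned": set("ACDEFGHIKLMNPQRSTVWYX*-"),
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


@dataclass
class SequenceRecord:
    """One sequence with a declared alphabet."""

    id: str
    residues: str
    description: str = ""
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.alphabet not in _ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        self.residues = self.residues.upper()
        bad = set(self.residues) - _ALPHABETS[self.alphabet]
        if bad:
            raise ValueError(
                f"record {self.id!r}: character(s) {sorted(bad)} outside "
                f"alphabet {self.alphabet!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """Single-isoform gene model; all segments (start, end) 1-based inclusive,
    sorted by genomic start regardless of strand."""

    gene_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_segments: list[tuple[int, int, int]]  # (start, end, phase)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        self.exons = sorted(self.exons)
        self.cds_segments = sorted(self.cds_segments)
        for segs in (self.exons, [(s, e) for s, e, _ in self.cds_segments]):
            for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
                if s2 <= e1:
                    raise ValueError(f"{self.gene_id}: overlapping segments")
        for s, e in self.exons:
            if e < s:
                raise ValueError(f"{self.gene_id}: exon end < start ({s},{e})")
        if not self.cds_segments:
            raise ValueError(f"{self.gene_id}: gene model without CDS")
        for s, e, _ in self.cds_segments:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValueError(
                    f"{self.gene_id}: CDS segment ({s},{e}) outside exon span"
                )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds_segments)


@dataclass(frozen=True)
class CodonTable:
    """Genetic code: 64 codons -> one-letter amino acid, stops mapped to 'TER'."""

    code_id: str
    forward: dict[str, str]
    stop_codons: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.forward) != 64:
            raise ValueError("codon table must cover all 64 codons")
        if any(self.forward[c] != "TER" for c in self.stop_codons):
            raise ValueError("stop codons must map to TER")


def standard_codon_table() -> CodonTable:
    """The standard genetic code (NCBI translation table 1)."""
    bio = _BioCodonTable.unambiguous_dna_by_id[1]
    forward = dict(bio.forward_table)
    for stop in bio.stop_codons:
        forward[stop] = "TER"
    return CodonTable("standard", forward, frozenset(bio.stop_codons))


# ----------------------------------------------------------------------------- FASTA


def _as_handle(source) -> TextIO:
    if isinstance(source, str):
        looks_like_content = (
            not source or source.startswith((">", "#")) or "\n" in source
        )
        return io.StringIO(source) if looks_like_content else open(source)
    return source


def read_fasta(source, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read FASTA from a path, string or text handle into SequenceRecords.

    Duplicate ids and characters outside ``alphabet`` raise ``ValueError``.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _as_handle(source) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            desc = rec.description[len(rec.id):].strip()
            records.append(
                SequenceRecord(rec.id, str(rec.seq), desc, alphabet=alphabet)
            )
    return records


def write_fasta(records: Iterable[SequenceRecord], target, width: int = 60) -> None:
    """Write FASTA wrapped at ``width`` columns to a path or text handle."""
    own = isinstance(target, str)
    handle = open(target, "w") if own else target
    try:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            handle.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i : i + width] + "\n")
    finally:
        if own:
            handle.close()


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ----------------------------------------------------------------------------- GFF3


def _gff_attributes(field9: str) -> dict[str, str]:
    out = {}
    for item in field9.strip().split(";"):
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(source) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS/UTR features into GeneModels.

    One isoform per gene is assumed; if several mRNAs exist the first in file
    order is kept.  An mRNA without CDS, a CDS outside the exon span, or a
    feature with end < start is an error.
    """
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    mrna_order: dict[str, list[str]] = {}
    with _as_handle(source) as handle:
        for line in handle:
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seq_id, _, ftype, start, end, _, strand, phase, attrs = cols
            start, end = int(start), int(end)
            if end < start:
                raise ValueError(f"feature with end < start: {line!r}")
            a = _gff_attributes(attrs)
            if ftype == "gene":
                gid = a.get("ID", f"gene{len(genes)}")
                genes[gid] = {
                    "seq_id": seq_id, "strand": strand,
                    "exons": [], "cds": [], "utr5": [], "utr3": [],
                }
                mrna_order[gid] = []
            elif ftype == "mRNA":
                parent = a.get("Parent")
                mid = a.get("ID", f"mRNA{len(mrna_parent)}")
                if parent in genes:
                    mrna_order[parent].append(mid)
                    mrna_parent[mid] = parent
            elif ftype in ("exon", "CDS", "five_prime_UTR", "three_prime_UTR"):
                parent = a.get("Parent")
                gid = mrna_parent.get(parent, parent)
                if gid not in genes:
                    continue
                # keep only the first isoform's features
                if parent in mrna_parent and mrna_order[gid] and parent != mrna_order[gid][0]:
                    continue
                if ftype == "exon":
                    genes[gid]["exons"].append((start, end))
                elif ftype == "CDS":
                    ph = int(phase) if phase in ("0", "1", "2") else 0
                    genes[gid]["cds"].append((start, end, ph))
                elif ftype == "five_prime_UTR":
                    genes[gid]["utr5"].append((start, end))
                else:
                    genes[gid]["utr3"].append((start, end))
    models = []
    for gid, g in genes.items():
        if not g["cds"]:
            raise ValueError(f"gene {gid!r}: mRNA without CDS")
        models.append(
            GeneModel(gid, g["seq_id"], g["strand"], g["exons"], g["cds"],
                      sorted(g["utr5"]), sorted(g["utr3"]))
        )
    return models


def write_gff3(models: Iterable[GeneModel], target) -> None:
    own = isinstance(target, str)
    handle = open(target, "w") if own else target
    try:
        handle.write("##gff-version 3\n")
        for m in models:
            s, e = m.span
            handle.write(f"{m.seq_id}\twoxkit\tgene\t{s}\t{e}\t.\t{m.strand}\t.\tID={m.gene_id}\n")
            mid = f"{m.gene_id}.t1"
            handle.write(f"{m.seq_id}\twoxkit\tmRNA\t{s}\t{e}\t.\t{m.strand}\t.\tID={mid};Parent={m.gene_id}\n")
            for xs, xe in m.exons:
                handle.write(f"{m.seq_id}\twoxkit\texon\t{xs}\t{xe}\t.\t{m.strand}\t.\tParent={mid}\n")
            for cs, ce, ph in m.cds_segments:
                handle.write(f"{m.seq_id}\twoxkit\tCDS\t{cs}\t{ce}\t.\t{m.strand}\t{ph}\tParent={mid}\n")
            for us, ue in m.utr5:
                handle.write(f"{m.seq_id}\twoxkit\tfive_prime_UTR\t{us}\t{ue}\t.\t{m.strand}\t.\tParent={mid}\n")
            for us, ue in m.utr3:
                handle.write(f"{m.seq_id}\twoxkit\tthree_prime_UTR\t{us}\t{ue}\t.\t{m.strand}\t.\tParent={mid}\n")
    finally:
        if own:
            handle.close()


# ------------------------------------------------------------------- CDS / translation


def extract_cds(genome: dict[str, SequenceRecord], model: GeneModel) -> SequenceRecord:
    """Concatenate CDS segments in genomic order; '-' strand is
    reverse-complemented once as a whole."""
    if model.seq_id not in genome:
        raise ValueError(f"{model.gene_id}: contig {model.seq_id!r} not in genome")
    contig = genome[model.seq_id].residues
    parts = []
    for s, e, _ in model.cds_segments:
        if e > len(contig) or s < 1:
            raise ValueError(
                f"{model.gene_id}: CDS segment ({s},{e}) beyond contig end"
            )
        parts.append(contig[s - 1 : e])
    cds = "".join(parts)
    if model.strand == "-":
        cds = reverse_complement(cds)
    if len(cds) % 3 != 0:
        raise ValueError(
            f"{model.gene_id}: CDS length {len(cds)} not divisible by 3"
        )
    return SequenceRecord(model.gene_id, cds, alphabet="dna")


def translate(cds: SequenceRecord, table: CodonTable | None = None) -> SequenceRecord:
    """Translate a CDS; a single trailing stop is dropped, codons containing
    non-ACGT become 'X', an internal stop raises naming the codon index."""
    table = table or standard_codon_table()
    seq = cds.residues
    if len(seq) % 3 != 0:
        raise ValueError(f"{cds.id}: length {len(seq)} not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    n = len(codons)
    aa = []
    for i, codon in enumerate(codons, start=1):
        if set(codon) - set("ACGT"):
            aa.append("X")
            continue
        res = table.forward[codon]
        if res == "TER":
            if i < n:
                raise ValueError(
                    f"{cds.id}: internal stop codon {codon} at codon {i}"
                )
            break  # trailing stop dropped
        aa.append(res)
    if not aa:
        raise ValueError(f"{cds.id}: translation is empty")
    return SequenceRecord(cds.id, "".join(aa), cds.description, alphabet="protein")


def has_trailing_stop(cds: SequenceRecord, table: CodonTable | None = None) -> bool:
    table = table or standard_codon_table()
    return len(cds.residues) >= 3 and cds.residues[-3:] in table.stop_codons


def read_tsv(source):
    """Small convenience wrapper: TSV with header row into a pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(source, sep="\t")
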