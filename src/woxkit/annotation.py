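"""Gene-structure statistics and promoter cis-element scanning.

Structure statistics summarize exon/intron/UTR composition per gene model;
genes spanning more than 3 kb are flagged as long.  Promoters are the
strand-corrected regions up to 2,000 bp upstream of the start codon.
Cis-elements are described as IUPAC consensus strings with a functional
category (stress / hormone / growth); scanning reports every match on both
strands, overlaps included, with positions 1-based on the promoter fragment
in gene orientation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .io_formats import GeneModel, SequenceRecord, reverse_complement

__all__ = [
    "GeneStructureStats",
    "MotifDefinition",
    "MotifHit",
    "PromoterRegion",
    "structure_stats",
    "structure_table",
    "extract_promoter",
    "scan_motifs",
    "summarize_elements",
    "read_motif_table",
    "demo_motif_table",
    "LONG_GENE_BP",
    "PROMOTER_LENGTH",
]

LONG_GENE_BP = 3000
PROMOTER_LENGTH = 2000

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass
class GeneStructureStats:
    gene_id: str
    n_exons: int
    n_introns: int
    has_utr5: bool
    has_utr3: bool
    span_bp: int
    long_gene: bool


@dataclass(frozen=True)
class MotifDefinition:
    """A named cis-element: IUPAC consensus plus functional category."""

    name: str
    iupac: str
    category: str

    def __post_init__(self) -> None:
        bad = set(self.iupac.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"motif {self.name!r}: invalid IUPAC code(s) {sorted(bad)}")
        if self.category not in ("stress", "hormone", "growth"):
            raise ValueError(f"motif {self.name!r}: unknown category {self.category!r}")


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif: str
    start: int  # 1-based on the promoter fragment
    strand: str
    matched: str


@dataclass
class PromoterRegion:
    gene_id: str
    sequence: str
    requested_length: int
    truncated: bool


def structure_stats(model: GeneModel) -> GeneStructureStats:
    """Exon/intron counts, UTR presence and gene span for one model."""
    s, e = model.span
    span = e - s + 1
    return GeneStructureStats(
        gene_id=model.gene_id,
        n_exons=len(model.exons),
        n_introns=len(model.exons) - 1,
        has_utr5=bool(model.utr5),
        has_utr3=bool(model.utr3),
        span_bp=span,
        long_gene=span > LONG_GENE_BP,
    )


def structure_table(models: list[GeneModel]) -> pd.DataFrame:
    rows = [vars(structure_stats(m)) for m in models]
    return pd.DataFrame(rows).set_index("gene_id")


def extract_promoter(
    genome: dict[str, SequenceRecord],
    model: GeneModel,
    length: int = PROMOTER_LENGTH,
) -> PromoterRegion:
    """Upstream region ending immediately before the start codon, read
    5'->3' in gene orientation; shorter than requested (truncated=True) when
    the contig ends first, an error when no upstream base exists at all."""
    if model.seq_id not in genome:
        raise ValueError(f"{model.gene_id}: contig {model.seq_id!r} not in genome")
    contig = genome[model.seq_id].residues
    if model.strand == "+":
        atg = model.cds_segments[0][0]  # first CDS base, 1-based
        start = max(1, atg - length)
        seq = contig[start - 1 : atg - 1]
    else:
        cds_end = model.cds_segments[-1][1]  # rightmost base = first in transcript
        end = min(len(contig), cds_end + length)
        seq = reverse_complement(contig[cds_end : end])
    if not seq:
        raise ValueError(f"{model.gene_id}: start codon at contig edge, no promoter")
    return PromoterRegion(model.gene_id, seq, length, truncated=len(seq) < length)


def _compile(motif: MotifDefinition) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported
    body = "".join(IUPAC[c] for c in motif.iupac.upper())
    return re.compile(f"(?=({body}))")


def scan_motifs(
    promoter: PromoterRegion | SequenceRecord,
    motifs: list[MotifDefinition],
) -> list[MotifHit]:
    """All matches of each consensus on both strands of a promoter.

    A minus-strand hit is an occurrence of the motif's reverse complement in
    the given sequence; its start is the leftmost matched base on the
    promoter fragment.  Hits are ordered by (start, strand, name).
    """
    gene_id = promoter.gene_id if isinstance(promoter, PromoterRegion) else promoter.id
    seq = (
        promoter.sequence if isinstance(promoter, PromoterRegion) else promoter.residues
    ).upper()
    hits: list[MotifHit] = []
    for motif in motifs:
        if len(motif.iupac) > len(seq):
            continue
        pattern = _compile(motif)
        for m in pattern.finditer(seq):
            hits.append(MotifHit(gene_id, motif.name, m.start() + 1, "+", m.group(1)))
        rc_pattern = re.compile(
            "(?=(" + "".join(IUPAC[c] for c in reverse_complement(motif.iupac.upper().replace("U", "T"))) + "))"
        )
        for m in rc_pattern.finditer(seq):
            hits.append(MotifHit(gene_id, motif.name, m.start() + 1, "-", m.group(1)))
    hits.sort(key=lambda h: (h.start, h.strand, h.motif))
    return hits


def summarize_elements(
    hits: list[MotifHit],
    motifs: list[MotifDefinition],
    gene_ids: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-gene per-motif and per-gene per-category hit counts.

    Genes listed in ``gene_ids`` appear even with zero hits.  Returns
    {'by_motif': ..., 'by_category': ...}; each frame carries a 'total' row.
    """
    by_name = {m.name: m for m in motifs}
    unknown = {h.motif for h in hits} - set(by_name)
    if unknown:
        raise ValueError(f"hits reference undefined motifs: {sorted(unknown)}")
    genes = list(gene_ids) if gene_ids is not None else sorted({h.gene_id for h in hits})
    categories = ["stress", "hormone", "growth"]
    motif_names = [m.name for m in motifs]
    by_motif = pd.DataFrame(0, index=genes, columns=motif_names)
    by_cat = pd.DataFrame(0, index=genes, columns=categories)
    for h in hits:
        if h.gene_id not in by_motif.index:
            continue
        by_motif.loc[h.gene_id, h.motif] += 1
        by_cat.loc[h.gene_id, by_name[h.motif].category] += 1
    by_motif.loc["total"] = by_motif.sum()
    by_cat.loc["total"] = by_cat.sum()
    return {"by_motif": by_motif, "by_category": by_cat}


def read_motif_table(source) -> list[MotifDefinition]:
    """Motif TSV with columns name, iupac, category."""
    df = pd.read_csv(source, sep="\t")
    return [
        MotifDefinition(r["name"], r["iupac"], r["category"])
        for _, r in df.iterrows()
    ]


def demo_motif_table() -> list[MotifDefinition]:
    """Small documented demo motif set shipped for tests and examples.

    Consensus strings are simplified cores of commonly scanned plant
    promoter elements; real studies should supply their own curated table.
    """
    path = resources.files("woxkit").joinpath("data", "demo_motifs.tsv")
    with path.open() as fh:
        return read_motif_table(fh)
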