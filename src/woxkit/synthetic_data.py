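"""Seeded generators for every input the pipeline consumes, with truth files.

Each generator is a pure function of (parameters, seed).  A single global
seed is expanded into independent per-generator substreams through a fixed
spawn-key scheme (one integer constant per generator, below), so adding a
generator never perturbs the data an existing one produces.

The generators emulate the *statistical* structure the analyses assume —
synonymous-codon bias per amino-acid family, substitutions accumulating
along a tree, 2-4-exon gene models with UTRs, promoters with planted
categorized elements, triplicate Ct tables with known fold changes — not
biological realism (protein evolution uses a uniform replacement model, no
rate heterogeneity, no repeats or isoforms).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .annotation import MotifDefinition
from .expression import CtTable
from .io_formats import GeneModel, SequenceRecord, reverse_complement
from .phylogeny import Alignment

__all__ = [
    "SimTruth",
    "simulate_cds_set",
    "simulate_alignment_on_tree",
    "simulate_annotation_bundle",
    "simulate_promoters",
    "simulate_ct_table",
]

# substream constants: spawn_key per generator
STREAM_CDS = 0
STREAM_ALIGNMENT = 1
STREAM_ANNOTATION = 2
STREAM_PROMOTERS = 3
STREAM_CT = 4

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_STOPS_DNA = ("TAA", "TAG", "TGA")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass
class SimTruth:
    """Ground truth serialized next to every generated dataset."""

    generator: str
    seed: int
    params: dict
    truth: dict = field(default_factory=dict)

    def to_json(self, target) -> None:
        own = isinstance(target, str)
        handle = open(target, "w") if own else target
        try:
            json.dump(dataclasses.asdict(self), handle, indent=1, default=str)
        finally:
            if own:
                handle.close()


# ------------------------------------------------------------------------- codon sets


def _dna_families() -> dict[str, list[str]]:
    """aa -> DNA codons, stops excluded (drawn separately)."""
    from .io_formats import standard_codon_table

    table = standard_codon_table()
    fams: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward.items()):
        if aa != "TER":
            fams.setdefault(aa, []).append(codon)
    return fams


def simulate_cds_set(
    n_genes: int,
    len_codons: int,
    family_probs: dict[str, dict[str, float]] | None = None,
    dirichlet_alpha: float | None = None,
    seed: int = 0,
) -> tuple[list[SequenceRecord], SimTruth]:
    """CDS sets with controllable synonymous-codon bias.

    Each gene is ATG + iid codons (amino acids uniform, codon within each
    family drawn from ``family_probs``) + one stop, so internal stops never
    occur by construction.  ``family_probs`` maps amino acid (or 'TER') to
    {DNA codon: probability summing to 1 within the family}; omitted
    families are uniform.  With ``dirichlet_alpha`` set, per-family
    probabilities are instead drawn once from a symmetric Dirichlet.
    """
    if len_codons < 3:
        raise ValueError("len_codons must be >= 3 (start + 1 codon + stop)")
    rng = _rng(seed, STREAM_CDS)
    fams = _dna_families()
    fams["TER"] = list(_STOPS_DNA)
    probs: dict[str, dict[str, float]] = {}
    for aa, codons in fams.items():
        if family_probs and aa in family_probs:
            p = np.array([family_probs[aa][c] for c in codons], dtype=float)
            if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                raise ValueError(f"family {aa!r}: probabilities must sum to 1")
        elif dirichlet_alpha is not None:
            p = rng.dirichlet([dirichlet_alpha] * len(codons))
        else:
            p = np.full(len(codons), 1.0 / len(codons))
        probs[aa] = dict(zip(codons, p))
    prob_vectors = {aa: np.array([probs[aa][c] for c in fams[aa]]) for aa in fams}
    records = []
    aa_list = list(AMINO_ACIDS)
    for g in range(n_genes):
        aas = rng.choice(aa_list, size=len_codons - 2)
        codons = np.empty(len_codons - 2, dtype=object)
        for aa in sorted(set(aas)):
            where = np.flatnonzero(aas == aa)
            fam = fams[aa]
            draws = rng.choice(len(fam), size=len(where), p=prob_vectors[aa])
            codons[where] = [fam[i] for i in draws]
        ter = fams["TER"]
        stop = ter[rng.choice(len(ter), p=prob_vectors["TER"])]
        records.append(
            SequenceRecord(
                f"g{g+1:04d}", "ATG" + "".join(codons) + stop, alphabet="dna"
            )
        )
    truth = SimTruth(
        "cds_set", seed,
        {"n_genes": n_genes, "len_codons": len_codons,
         "dirichlet_alpha": dirichlet_alpha},
        {"family_probs": {aa: dict(p) for aa, p in probs.items()}},
    )
    return records, truth


# ------------------------------------------------------------------- tree alignments


def simulate_alignment_on_tree(
    newick: str,
    n_columns: int,
    subs_rate: float,
    seed: int = 0,
) -> tuple[Alignment, SimTruth]:
    """Evolve a protein alignment down a tree with branch lengths.

    The root sequence is uniform over the 20 residues; each branch receives
    Poisson(rate * branch_length * n_columns) substitutions at uniform
    positions, each replacing the residue with a uniform draw from the other
    19 (multiple hits per site allowed).
    """
    rng = _rng(seed, STREAM_ALIGNMENT)
    tree = dendropy.Tree.get(data=newick, schema="newick")
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    root_seq = rng.integers(0, 20, size=n_columns)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    records = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            seq = root_seq
        else:
            seq = seqs[id(node.parent_node)].copy()
            bl = node.edge.length or 0.0
            n_subs = rng.poisson(subs_rate * bl * n_columns)
            for _ in range(n_subs):
                pos = rng.integers(0, n_columns)
                new = rng.integers(0, 19)
                if new >= seq[pos]:
                    new += 1
                seq[pos] = new
            seqs[id(node)] = seq
        if node.is_leaf():
            residues = b"".join(aa[i] for i in seq).decode()
            records.append(
                SequenceRecord(node.taxon.label, residues, alphabet="protein-aligned")
            )
    truth = SimTruth(
        "alignment_on_tree", seed,
        {"n_columns": n_columns, "subs_rate": subs_rate},
        {"true_tree_newick": newick},
    )
    return Alignment(records), truth


# ----------------------------------------------------------------- annotation bundles


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + one stop."""
    non_stop = [
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in _STOPS_DNA
    ]
    body = [non_stop[i] for i in rng.integers(0, len(non_stop), size=n_codons - 2)]
    stop = _STOPS_DNA[rng.integers(0, 3)]
    return "ATG" + "".join(body) + stop


def _mirror(interval: tuple[int, int], length: int) -> tuple[int, int]:
    s, e = interval
    return length - e + 1, length - s + 1


def simulate_annotation_bundle(
    n_genes: int,
    exon_count_range: tuple[int, int] = (2, 4),
    seed: int = 0,
) -> tuple[SequenceRecord, list[GeneModel], SimTruth]:
    """Toy genome + single-isoform gene models with UTRs on one contig.

    Strands alternate (+, -, +, ...).  Transcripts are UTR5 + CDS + UTR3
    split over the requested exon count with 100-800 bp introns; the truth
    table records each gene's exon count, span and exact CDS, so extraction
    and structure statistics can be checked against it.
    """
    lo, hi = exon_count_range
    if not (1 <= lo <= hi <= 10):
        raise ValueError("exon_count_range must lie within [1, 10]")
    rng = _rng(seed, STREAM_ANNOTATION)
    contig_parts: list[str] = []
    models: list[GeneModel] = []
    truth_genes = {}
    cursor = 0  # 0-based length of contig built so far
    for g in range(n_genes):
        gap = int(rng.integers(200, 1001))
        contig_parts.append(_random_dna(rng, gap))
        cursor += gap
        strand = "+" if g % 2 == 0 else "-"
        n_exons = int(rng.integers(lo, hi + 1))
        utr5 = int(rng.integers(40, 201))
        utr3 = int(rng.integers(40, 201))
        n_codons = int(rng.integers(80, 401))
        cds = _random_cds(rng, n_codons)
        transcript = _random_dna(rng, utr5) + cds + _random_dna(rng, utr3)
        t_len = len(transcript)
        # split transcript into n_exons pieces, each >= 20 nt
        while True:
            cuts = sorted(rng.integers(20, t_len - 19, size=n_exons - 1).tolist())
            bounds = [0] + cuts + [t_len]
            if all(b2 - b1 >= 20 for b1, b2 in zip(bounds, bounds[1:])):
                break
        introns = [int(rng.integers(100, 801)) for _ in range(n_exons - 1)]
        # local plus-strand canvas for this gene
        local_seq: list[str] = []
        exons_local: list[tuple[int, int]] = []
        pos = 0  # 0-based within local canvas
        exon_tx: list[tuple[int, int]] = []  # transcript coords per exon (1-based)
        for i, (b1, b2) in enumerate(zip(bounds, bounds[1:])):
            local_seq.append(transcript[b1:b2])
            exons_local.append((pos + 1, pos + (b2 - b1)))
            exon_tx.append((b1 + 1, b2))
            pos += b2 - b1
            if i < n_exons - 1:
                local_seq.append(_random_dna(rng, introns[i]))
                pos += introns[i]
        local = "".join(local_seq)
        L = len(local)

        def tx_to_local(t: int) -> int:
            for (ls, le), (ts, te) in zip(exons_local, exon_tx):
                if ts <= t <= te:
                    return ls + (t - ts)
            raise AssertionError

        cds_tx = (utr5 + 1, utr5 + len(cds))
        utr5_tx = (1, utr5)
        utr3_tx = (utr5 + len(cds) + 1, t_len)

        def tx_interval_to_local(ts: int, te: int) -> list[tuple[int, int]]:
            out = []
            for (ls, le), (xs, xe) in zip(exons_local, exon_tx):
                s, e = max(ts, xs), min(te, xe)
                if s <= e:
                    out.append((tx_to_local(s), tx_to_local(e)))
            return out

        cds_local = tx_interval_to_local(*cds_tx)
        utr5_local = tx_interval_to_local(*utr5_tx)
        utr3_local = tx_interval_to_local(*utr3_tx)
        if strand == "-":
            local = reverse_complement(local)
            exons_local = sorted(_mirror(iv, L) for iv in exons_local)
            cds_local = sorted(_mirror(iv, L) for iv in cds_local)
            utr5_local = sorted(_mirror(iv, L) for iv in utr5_local)
            utr3_local = sorted(_mirror(iv, L) for iv in utr3_local)
        # phases in transcript order
        tx_order = cds_local if strand == "+" else list(reversed(cds_local))
        phased = {}
        cum = 0
        for s, e in tx_order:
            phased[(s, e)] = (3 - cum % 3) % 3
            cum += e - s + 1
        cds_segments = [(s, e, phased[(s, e)]) for s, e in cds_local]

        offset = cursor  # local coordinate 1 == contig coordinate offset+1
        gene_id = f"gene{g+1:03d}"
        model = GeneModel(
            gene_id, "contig1", strand,
            [(s + offset, e + offset) for s, e in exons_local],
            [(s + offset, e + offset, ph) for s, e, ph in cds_segments],
            [(s + offset, e + offset) for s, e in utr5_local],
            [(s + offset, e + offset) for s, e in utr3_local],
        )
        models.append(model)
        contig_parts.append(local)
        cursor += L
        truth_genes[gene_id] = {
            "strand": strand, "n_exons": n_exons,
            "span_bp": L, "cds": cds,
        }
    contig_parts.append(_random_dna(rng, int(rng.integers(200, 1001))))
    genome = SequenceRecord("contig1", "".join(contig_parts), alphabet="dna")
    truth = SimTruth(
        "annotation_bundle", seed,
        {"n_genes": n_genes, "exon_count_range": list(exon_count_range)},
        {"genes": truth_genes},
    )
    return genome, models, truth


# ------------------------------------------------------------------------- promoters


def simulate_promoters(
    n: int,
    plant_spec: dict[str, int],
    motifs: list[MotifDefinition],
    length: int = 2000,
    background_alphabet: str = "ACGT",
    seed: int = 0,
) -> tuple[list[SequenceRecord], SimTruth]:
    """Promoters with planted motifs at non-overlapping, non-adjacent slots.

    ``plant_spec`` gives per-promoter counts per motif name (identical for
    every promoter).  Placement uses disjoint slots separated by at least
    one background base, so planted instances cannot merge into extra
    matches; strands are random.  With a background alphabet disjoint from
    the motif letters (and their complements), scan counts recover the
    planted counts exactly.
    """
    by_name = {m.name: m for m in motifs}
    unknown = set(plant_spec) - set(by_name)
    if unknown:
        raise ValueError(f"plant_spec references undefined motifs: {sorted(unknown)}")
    rng = _rng(seed, STREAM_PROMOTERS)
    max_len = max((len(by_name[name].iupac) for name in plant_spec), default=1)
    slot = max_len + 1
    n_slots = length // slot
    total = sum(plant_spec.values())
    if total > n_slots:
        raise ValueError(
            f"cannot pack {total} motifs of width <= {max_len} into {length} bp"
        )
    bg = np.array(list(background_alphabet))
    records = []
    placements: dict[str, list] = {}
    for i in range(n):
        seq = list("".join(bg[rng.integers(0, len(bg), size=length)]))
        slots = rng.permutation(n_slots)[:total]
        placed = []
        k = 0
        for name, count in sorted(plant_spec.items()):
            consensus = by_name[name].iupac.upper().replace("U", "T")
            for _ in range(count):
                start = int(slots[k]) * slot  # 0-based
                k += 1
                strand = "+" if rng.random() < 0.5 else "-"
                inst = consensus if strand == "+" else reverse_complement(consensus)
                seq[start : start + len(inst)] = list(inst)
                placed.append({"motif": name, "start": start + 1, "strand": strand})
        rec_id = f"prom{i+1:03d}"
        records.append(SequenceRecord(rec_id, "".join(seq), alphabet="dna"))
        placements[rec_id] = sorted(placed, key=lambda p: p["start"])
    truth = SimTruth(
        "promoters", seed,
        {"n": n, "length": length, "background_alphabet": background_alphabet},
        {"planted_counts": dict(sorted(plant_spec.items())),
         "placements": placements},
    )
    return records, truth


# -------------------------------------------------------------------------- Ct tables


def simulate_ct_table(
    true_folds: dict[str, dict[str, float]],
    calibrator: str,
    ref_ct: float = 20.0,
    baseline_delta: float = 2.0,
    noise_sd: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
    references: tuple[str, str] = ("JcGAPDH", "JcActin"),
) -> tuple[CtTable, SimTruth]:
    """Triplicate-style Ct tables with known fold changes.

    ``true_folds[gene][sample]`` is the fold change vs the calibrator (the
    calibrator entry should be 1).  Target Ct = ref_ct + baseline_delta -
    log2(fold) + N(0, sd); both reference genes sit at ref_ct + N(0, sd) in
    every sample.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(seed, STREAM_CT)
    samples = sorted({s for folds in true_folds.values() for s in folds})
    if calibrator not in samples:
        raise ValueError(f"calibrator {calibrator!r} absent from true_folds")
    rows = []
    for gene in sorted(true_folds):
        for sample in samples:
            fold = true_folds[gene][sample]
            if fold <= 0:
                raise ValueError("fold changes must be positive")
            base = ref_ct + baseline_delta - np.log2(fold)
            for rep in range(1, replicates + 1):
                rows.append(
                    {"gene_id": gene, "sample_id": sample, "replicate": rep,
                     "ct": base + rng.normal(0.0, noise_sd) if noise_sd else base}
                )
    for ref in references:
        for sample in samples:
            for rep in range(1, replicates + 1):
                rows.append(
                    {"gene_id": ref, "sample_id": sample, "replicate": rep,
                     "ct": ref_ct + rng.normal(0.0, noise_sd) if noise_sd else ref_ct}
                )
    table = CtTable(pd.DataFrame(rows), list(references), calibrator)
    truth = SimTruth(
        "ct_table", seed,
        {"ref_ct": ref_ct, "baseline_delta": baseline_delta,
         "noise_sd": noise_sd, "replicates": replicates},
        {"true_folds": {g: dict(f) for g, f in true_folds.items()},
         "calibrator": calibrator},
    )
    return table, truth
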