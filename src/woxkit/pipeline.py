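"""End-to-end orchestration and worked-example verification.

``run_pipeline`` executes whichever stages the configuration provides
inputs for (codon usage, protein profiles, phylogeny + clades, gene
structure + promoter scan, expression) and writes one TSV per result next
to a JSON run report.  ``verify_fixtures`` recomputes the published
classification counts from the transcribed codon-usage tables and compares
them with the printed claims — the package's desk-scale worked example.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation, codon_usage, expression, phylogeny, protparam
from .io_formats import read_fasta, read_gff3

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "verify_fixtures"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; every analysis constant is a named,
    overridable setting."""

    out_dir: str = "woxkit_out"
    seed: int = 0
    # inputs (all optional; stages lacking inputs are skipped)
    cds: dict[str, str] = field(default_factory=dict)       # label -> FASTA
    ref_freqs: dict[str, str] = field(default_factory=dict) # label -> TSV codon,freq
    proteins: str | None = None
    alignment: str | None = None
    anchors: str | None = None                              # TSV anchor_id,clade
    gff: str | None = None
    genome: str | None = None
    motifs: str | None = None
    expression_matrix: str | None = None
    ct_table: str | None = None
    references: list[str] = field(default_factory=lambda: ["JcGAPDH", "JcActin"])
    calibrator: str | None = None
    # thresholds (the analysis constants)
    hf_60: float = 60.0
    hf_mult: float = 1.5
    ratio_lo: float = 0.5
    ratio_hi: float = 2.0
    long_gene_bp: int = 3000
    promoter_len: int = 2000
    bootstrap_reps: int = 1000
    distance_model: str = "p"
    transform: str = "row_z"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunReport:
    stages: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    input_checksums: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(not s.startswith("failed") for s in self.stages.values())

    def to_json(self, target) -> None:
        own = isinstance(target, (str, Path))
        handle = open(target, "w") if own else target
        try:
            json.dump(dataclasses.asdict(self), handle, indent=1)
        finally:
            if own:
                handle.close()


def _checksum(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage the config has inputs for; a failing stage is
    recorded and its dependents skipped, but the report is always written."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    report.thresholds = {
        "hf_60": config.hf_60, "hf_mult": config.hf_mult,
        "ratio_lo": config.ratio_lo, "ratio_hi": config.ratio_hi,
        "long_gene_bp": config.long_gene_bp,
        "promoter_len": config.promoter_len,
        "bootstrap_reps": config.bootstrap_reps,
    }
    for name, path in {
        **{f"cds:{k}": v for k, v in config.cds.items()},
        "proteins": config.proteins, "alignment": config.alignment,
        "gff": config.gff, "genome": config.genome, "motifs": config.motifs,
        "expression_matrix": config.expression_matrix, "ct_table": config.ct_table,
    }.items():
        if path:
            report.input_checksums[name] = _checksum(path)

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=index, float_format="%.6g")
        report.outputs.append(str(path))

    # --- codon usage ---------------------------------------------------------
    if config.cds:
        try:
            usage_tables = {}
            freqs = {}
            for label, path in config.cds.items():
                counts = codon_usage.count_codons(read_fasta(path), label)
                usage_tables[label] = codon_usage.compute_usage(counts)
                freqs[label] = codon_usage.codon_frequency(counts)
                emit(f"usage_{label}.tsv", usage_tables[label].df.reset_index())
            if len(usage_tables) > 1:
                npos, nneg, nnone, ndiff = codon_usage.bias_partition(
                    list(usage_tables.values())
                )
                consensus = codon_usage.consensus_high_frequency(
                    list(usage_tables.values())
                )
                emit(
                    "bias_summary.tsv",
                    pd.DataFrame(
                        [{"positive_all": npos, "negative_all": nneg,
                          "none_all": nnone, "differing": ndiff,
                          "consensus_high_frequency": ",".join(sorted(consensus))}]
                    ),
                )
            if config.ref_freqs:
                refs = {}
                for rlabel, rpath in config.ref_freqs.items():
                    rdf = pd.read_csv(rpath, sep="\t")
                    refs[rlabel] = dict(zip(rdf["codon"], rdf["freq"]))
                rank_rows = []
                for label, freq in freqs.items():
                    for rlabel, ref in refs.items():
                        table = codon_usage.ratio_compare(
                            freq, ref, f"{label}/{rlabel}",
                            lo=config.ratio_lo, hi=config.ratio_hi,
                        )
                        emit(f"ratios_{label}_{rlabel}.tsv", table.df.reset_index())
                    for host, n_div, mean_log in codon_usage.rank_hosts(
                        freq, refs, lo=config.ratio_lo, hi=config.ratio_hi
                    ):
                        rank_rows.append(
                            {"gene_set": label, "host": host,
                             "n_divergent": n_div, "mean_abs_log2_ratio": mean_log}
                        )
                emit("host_ranking.tsv", pd.DataFrame(rank_rows))
            report.stages["codon_usage"] = "ok"
        except Exception as exc:  # noqa: BLE001 - report and continue
            report.stages["codon_usage"] = f"failed: {exc}"
    else:
        report.stages["codon_usage"] = "skipped"

    # --- protein profiles ----------------------------------------------------
    if config.proteins:
        try:
            records = read_fasta(config.proteins, alphabet="protein")
            emit("protein_profile.tsv", protparam.profile_batch(records))
            report.stages["protparam"] = "ok"
        except Exception as exc:
            report.stages["protparam"] = f"failed: {exc}"
    else:
        report.stages["protparam"] = "skipped"

    # --- phylogeny -----------------------------------------------------------
    if config.alignment:
        try:
            aln = phylogeny.Alignment(
                read_fasta(config.alignment, alphabet="protein-aligned")
            )
            tree = phylogeny.bootstrap_support(
                aln, model=config.distance_model,
                n_reps=config.bootstrap_reps, seed=config.seed,
            )
            tree_path = out / "tree.nwk"
            tree.write(path=str(tree_path), schema="newick",
                       suppress_rooting=True)
            report.outputs.append(str(tree_path))
            if config.anchors:
                adf = pd.read_csv(config.anchors, sep="\t")
                anchors = dict(zip(adf["anchor_id"], adf["clade"]))
                dm = phylogeny.pairwise_distance(aln, config.distance_model)
                emit("clades.tsv", phylogeny.assign_clades(dm, anchors), index=True)
            report.stages["phylogeny"] = "ok"
        except Exception as exc:
            report.stages["phylogeny"] = f"failed: {exc}"
    else:
        report.stages["phylogeny"] = "skipped"

    # --- annotation ----------------------------------------------------------
    if config.gff:
        try:
            models = read_gff3(config.gff)
            emit("structure.tsv", annotation.structure_table(models), index=True)
            if config.genome and config.motifs:
                genome = {r.id: r for r in read_fasta(config.genome)}
                motifs = annotation.read_motif_table(config.motifs)
                hits = []
                for model in models:
                    promoter = annotation.extract_promoter(
                        genome, model, length=config.promoter_len
                    )
                    hits.extend(annotation.scan_motifs(promoter, motifs))
                emit("promoter_hits.tsv", pd.DataFrame([vars(h) for h in hits]))
                summary = annotation.summarize_elements(
                    hits, motifs, [m.gene_id for m in models]
                )
                emit("element_summary.tsv", summary["by_category"], index=True)
            report.stages["annotation"] = "ok"
        except Exception as exc:
            report.stages["annotation"] = f"failed: {exc}"
    else:
        report.stages["annotation"] = "skipped"

    # --- expression ----------------------------------------------------------
    if config.expression_matrix or config.ct_table:
        try:
            if config.expression_matrix:
                expr = pd.read_csv(config.expression_matrix, sep="\t", index_col=0)
                emit(
                    f"expression_{config.transform}.tsv",
                    expression.transform_matrix(expr, config.transform),
                    index=True,
                )
                emit("stage_profile.tsv", expression.stage_profile(expr), index=True)
            if config.ct_table:
                ct = expression.CtTable(
                    pd.read_csv(config.ct_table, sep="\t"),
                    config.references,
                    config.calibrator,
                )
                emit("qpcr_folds.tsv", expression.relative_expression(ct).table)
            report.stages["expression"] = "ok"
        except Exception as exc:
            report.stages["expression"] = f"failed: {exc}"
    else:
        report.stages["expression"] = "skipped"

    report.to_json(out / "run_report.json")
    return report


# --------------------------------------------------------------- worked example checks

# Printed claims the transcribed tables must reproduce.
_EXPECTED_BIAS_PARTITION = (19, 23, 2, 20)
_EXPECTED_CONSENSUS_HF = {"GCA", "GAU", "CCA", "AGA"}
_EXPECTED_DIVERGENT = {
    "JcWOX/At": 6,
    "HbWOX/Pt": 6,
    "MeWOX/Nt": 5,
    "RcWOX/Pt": 5,
}
_EXPECTED_CLADE_SIZES = {"modern": 38, "intermediate": 12, "ancient": 9}
_EXPECTED_CLADE_PCT = {"modern": 64.4, "intermediate": 20.3, "ancient": 15.3}


def verify_fixtures(fixture_dir: str | None = None) -> pd.DataFrame:
    """Recompute the published classification counts from the transcribed
    usage/ratio tables and compare with the printed claims.

    Returns a DataFrame with columns check, expected, observed, passed.
    With ``fixture_dir`` set, the two fixture TSVs are read from there
    instead of the packaged copies.
    """
    if fixture_dir is not None:
        d = Path(fixture_dir)
        t1 = d / "table1_rscu_rfsc.tsv"
        t2 = d / "table2_ratios.tsv"
        if not t1.exists() or not t2.exists():
            raise FileNotFoundError(f"fixture TSVs not found under {fixture_dir!r}")
        df1 = pd.read_csv(t1, sep="\t")
        usage = {
            label: codon_usage.usage_from_printed(
                label,
                dict(zip(df1["codon"], df1[f"{p}_rscu"])),
                dict(zip(df1["codon"], df1[f"{p}_rfsc"])),
            )
            for label, p in zip(
                ("HbWOX", "JcWOX", "MeWOX", "RcWOX"), ("hb", "jc", "me", "rc")
            )
        }
        df2 = pd.read_csv(t2, sep="\t")
        ratios = {
            key: codon_usage.ratio_from_printed(
                key, dict(zip(df2["codon"], df2[col]))
            )
            for key, col in (
                ("JcWOX/At", "jc_at"), ("HbWOX/Pt", "hb_pt"),
                ("MeWOX/Nt", "me_nt"), ("RcWOX/Pt", "rc_pt"),
            )
        }
    else:
        usage = codon_usage.load_fixture_usage_tables()
        ratios = codon_usage.load_fixture_ratio_tables()

    checks = []

    def record(check: str, expected, observed) -> None:
        checks.append(
            {"check": check, "expected": str(expected), "observed": str(observed),
             "passed": expected == observed}
        )

    record("bias_partition", _EXPECTED_BIAS_PARTITION,
           codon_usage.bias_partition(list(usage.values())))
    record("consensus_high_frequency", sorted(_EXPECTED_CONSENSUS_HF),
           sorted(codon_usage.consensus_high_frequency(list(usage.values()))))
    for key, expected in _EXPECTED_DIVERGENT.items():
        record(f"divergent_codons:{key}", expected, ratios[key].n_divergent)
    record("clade_proportions", _EXPECTED_CLADE_PCT,
           phylogeny.clade_proportions(_EXPECTED_CLADE_SIZES))
    return pd.DataFrame(checks)
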