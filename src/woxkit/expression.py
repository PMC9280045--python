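"""Expression-matrix transforms and 2^-ddCt relative expression.

qPCR fold changes use the comparative Ct method with two reference genes:
per sample, dCt = mean target Ct minus the mean of the two reference genes'
mean Ct (arithmetic mean of Ct, i.e. geometric mean of linear quantities);
ddCt is taken against a calibrator sample and fold = 2^-ddCt, assuming
amplification efficiency 2.  Significance of each sample against the
calibrator is a two-sided Student's t-test on replicate-level dCt values at
alpha = 0.01, with no multiple-testing correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtTable",
    "RelativeExpression",
    "relative_expression",
    "transform_matrix",
    "stage_profile",
    "ALPHA",
]

ALPHA = 0.01


@dataclass
class CtTable:
    """Long-format qPCR Ct values.

    ``data`` columns: gene_id, sample_id, replicate, ct.  ``references``
    names the reference genes (present in every sample); ``calibrator`` is
    the sample all fold changes are expressed against.
    """

    data: pd.DataFrame
    references: list[str]
    calibrator: str

    def __post_init__(self) -> None:
        required = {"gene_id", "sample_id", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing column(s): {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        if self.calibrator not in set(self.data["sample_id"]):
            raise ValueError(f"calibrator sample {self.calibrator!r} absent")
        samples = set(self.data["sample_id"])
        for ref in self.references:
            ref_samples = set(self.data.loc[self.data["gene_id"] == ref, "sample_id"])
            if ref_samples != samples:
                raise ValueError(
                    f"reference gene {ref!r} missing from sample(s) "
                    f"{sorted(samples - ref_samples)}"
                )

    @property
    def targets(self) -> list[str]:
        return sorted(set(self.data["gene_id"]) - set(self.references))

    @property
    def samples(self) -> list[str]:
        return sorted(set(self.data["sample_id"]))


@dataclass
class RelativeExpression:
    """Fold changes (2^-ddCt) per gene x sample, with the calibrator column
    identically 1; ``table`` columns: gene_id, sample_id, fold, p_value,
    significant, n_replicates, test_skipped."""

    table: pd.DataFrame
    calibrator: str

    def fold(self, gene: str, sample: str) -> float:
        sel = self.table[
            (self.table["gene_id"] == gene) & (self.table["sample_id"] == sample)
        ]
        return float(sel["fold"].iloc[0])

    def fold_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="gene_id", columns="sample_id", values="fold")


def _ref_aggregate(ct: CtTable, sample: str) -> float:
    per_ref = []
    for ref in ct.references:
        vals = ct.data.loc[
            (ct.data["gene_id"] == ref) & (ct.data["sample_id"] == sample), "ct"
        ]
        per_ref.append(vals.mean())
    return float(np.mean(per_ref))


def relative_expression(ct: CtTable) -> RelativeExpression:
    """2^-ddCt fold change of every target gene in every sample vs the
    calibrator, plus a replicate-level t-test against the calibrator.

    With a single replicate in either sample the fold is still computed but
    the test is skipped and flagged.
    """
    rows = []
    for gene in ct.targets:
        per_sample_dct: dict[str, np.ndarray] = {}
        for sample in ct.samples:
            target = ct.data.loc[
                (ct.data["gene_id"] == gene) & (ct.data["sample_id"] == sample), "ct"
            ].to_numpy()
            if len(target) == 0:
                continue
            per_sample_dct[sample] = target - _ref_aggregate(ct, sample)
        if ct.calibrator not in per_sample_dct:
            raise ValueError(f"gene {gene!r} has no Ct in calibrator sample")
        cal = per_sample_dct[ct.calibrator]
        for sample, dct in per_sample_dct.items():
            ddct = dct.mean() - cal.mean()
            fold = 2.0 ** (-ddct)
            skipped = len(dct) < 2 or len(cal) < 2
            if sample == ct.calibrator:
                p = 1.0
            elif skipped:
                p = float("nan")
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    p = float(stats.ttest_ind(dct, cal).pvalue)
                if np.isnan(p):  # zero variance in both groups
                    p = 1.0 if np.isclose(dct.mean(), cal.mean()) else 0.0
            rows.append(
                {
                    "gene_id": gene,
                    "sample_id": sample,
                    "fold": fold,
                    "p_value": p,
                    "significant": bool(p < ALPHA) if not np.isnan(p) else False,
                    "n_replicates": len(dct),
                    "test_skipped": skipped and sample != ct.calibrator,
                }
            )
    return RelativeExpression(pd.DataFrame(rows), ct.calibrator)


def transform_matrix(expr: pd.DataFrame, mode: str = "log2p1") -> pd.DataFrame:
    """Heatmap-style transforms of a genes x samples abundance matrix.

    ``log2p1``: x -> log2(x+1).  ``row_z``: log2(x+1) then per-row z-score;
    constant rows get z = 0 and are flagged in ``result.attrs['constant_rows']``.
    """
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression matrix contains negative entries")
    logged = np.log2(expr + 1.0)
    if mode == "log2p1":
        return logged
    if mode == "row_z":
        mean = logged.mean(axis=1)
        sd = logged.std(axis=1, ddof=1)
        constant = sd == 0
        sd = sd.replace(0, 1.0)
        z = logged.sub(mean, axis=0).div(sd, axis=0)
        z[constant] = 0.0
        z.attrs["constant_rows"] = list(expr.index[constant])
        return z
    raise ValueError(f"unknown transform mode {mode!r}")


def stage_profile(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene peak stage and monotonic-decrease flag across ordered samples.

    The peak is the argmax sample (ties -> earliest column); ``decreasing``
    is True only when every successive stage is strictly lower.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least two samples/stages")
    values = expr.to_numpy()
    peak_idx = values.argmax(axis=1)  # argmax returns the first maximum
    decreasing = (np.diff(values, axis=1) < 0).all(axis=1)
    return pd.DataFrame(
        {
            "peak_sample": [expr.columns[i] for i in peak_idx],
            "decreasing": decreasing,
        },
        index=expr.index,
    )
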