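"""Relative expression (ddCT) and copy-number estimation from qPCR Ct values.

Pure ddCT quantification with a fixed per-cycle amplification factor of 2:
per sample, dCt = mean Ct(target) - mean Ct(reference); ddCt subtracts the
calibrator sample's dCt; the relative quantity is RQ = 2^(-ddCt).  Copy
number uses the same arithmetic against a single-copy control assay,
scaled by the calibrator's known copy count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QpcrTable",
    "ddct_relative_expression",
    "cnv_estimate",
]


@dataclass
class QpcrTable:
    """Replicate-level Ct records with a designated calibrator sample.

    ``data`` columns: sample, assay, replicate, ct_target, ct_reference.
    ``role`` is 'expression' or 'cnv' (reference = endogenous control gene
    or single-copy control assay respectively).
    """

    data: pd.DataFrame
    calibrator: str
    role: str = "expression"

    REQUIRED = ("sample", "assay", "replicate", "ct_target", "ct_reference")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"qPCR table missing columns: {missing}")
        if self.role not in ("expression", "cnv"):
            raise ValueError("role must be 'expression' or 'cnv'")
        ct = self.data[["ct_target", "ct_reference"]].to_numpy(dtype=float)
        if (ct[np.isfinite(ct)] <= 0).any():
            raise ValueError("Ct values must be positive")
        if self.calibrator not in set(self.data["sample"]):
            raise ValueError(f"calibrator sample {self.calibrator!r} absent from table")

    @classmethod
    def read_csv(cls, path, calibrator: str, role: str = "expression") -> "QpcrTable":
        return cls(pd.read_csv(path, comment="#"), calibrator=calibrator, role=role)


def _sample_dct(group: pd.DataFrame) -> tuple[float, np.ndarray]:
    """Mean dCt for a (sample, assay) group and replicate-level dCt values."""
    tgt = group["ct_target"].to_numpy(dtype=float)
    ref = group["ct_reference"].to_numpy(dtype=float)
    ok = np.isfinite(tgt) & np.isfinite(ref)
    dct_mean = float(np.nanmean(tgt) - np.nanmean(ref))
    return dct_mean, tgt[ok] - ref[ok]


def ddct_relative_expression(table: QpcrTable) -> pd.DataFrame:
    """Per-(sample, assay) relative quantity RQ = 2^(-ddCt) with dispersion.

    The dispersion column ``sd`` is the standard deviation of the
    replicate-level RQ values (each replicate pairing its own target and
    reference Ct).  Samples lacking a finite reference Ct are skipped
    with a warning.  The calibrator's RQ is 1 by construction.
    """
    results = []
    cal_dct: dict[str, float] = {}
    for assay, sub in table.data.groupby("assay", sort=True):
        cal = sub[sub["sample"] == table.calibrator]
        if cal.empty or not np.isfinite(cal["ct_reference"].to_numpy(dtype=float)).any():
            raise ValueError(
                f"calibrator {table.calibrator!r} has no valid Ct for assay {assay!r}"
            )
        cal_dct[assay], _ = _sample_dct(cal)
    for (sample, assay), group in table.data.groupby(["sample", "assay"], sort=True):
        ref = group["ct_reference"].to_numpy(dtype=float)
        if not np.isfinite(ref).any():
            warnings.warn(f"sample {sample!r} (assay {assay!r}) lacks reference Ct; skipped")
            continue
        dct, dct_reps = _sample_dct(group)
        ddct = dct - cal_dct[assay]
        rq = 2.0 ** (-ddct)
        rq_reps = 2.0 ** (-(dct_reps - cal_dct[assay]))
        sd = float(np.std(rq_reps, ddof=1)) if rq_reps.size > 1 else 0.0
        results.append(
            {
                "sample": sample,
                "assay": assay,
                "ddct": float(ddct),
                "rq": float(rq),
                "sd": sd,
                "n_replicates": int(len(group)),
            }
        )
    return pd.DataFrame(results)


def cnv_estimate(
    table: QpcrTable, calibrator_copies: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-assay copy-number estimates and a per-sample consensus.

    Copies = RQ x ``calibrator_copies`` where RQ is the ddCT relative
    quantity against the single-copy control assay, normalized to the
    calibrator sample.  The consensus is the arithmetic mean over assays,
    rounded to the nearest integer only in the summary column; samples
    whose assays disagree by more than 2-fold are flagged and their
    consensus withheld.
    """
    per_assay = ddct_relative_expression(table).copy()
    per_assay["copies"] = per_assay["rq"] * calibrator_copies
    rows = []
    for sample, sub in per_assay.groupby("sample", sort=True):
        vals = sub["copies"].to_numpy(dtype=float)
        flagged = bool(vals.size > 1 and vals.max() / max(vals.min(), 1e-300) > 2.0)
        if flagged:
            warnings.warn(f"sample {sample!r}: assays disagree >2-fold; consensus withheld")
        consensus = np.nan if flagged else float(vals.mean())
        rows.append(
            {
                "sample": sample,
                "consensus": consensus,
                "consensus_rounded": np.nan if flagged else int(round(consensus)),
                "flagged": flagged,
            }
        )
    return per_assay[["sample", "assay", "rq", "copies", "sd"]], pd.DataFrame(rows)
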