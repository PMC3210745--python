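"""ddCt double-normalization arithmetic and replicate QC for qPCR validation.

Fold enrichment of a candidate breakpoint locus in apoptotic (fragmented) DNA
is computed by double normalization: against uncut genomic DNA at the same
locus (controls for copy-number aberrations) and against a negative-control
primer pair in a region without apoptotic cleavage (controls for loading):

    dCt_apop = Ct(target, apoptotic) - Ct(negctrl, apoptotic)
    dCt_gen  = Ct(target, genomic)   - Ct(negctrl, genomic)
    ddCt     = dCt_apop - dCt_gen
    fold     = 2 ** (-ddCt)

Replicate means feed the ddCt; the QC rule requires the technical-replicate
standard error of each Ct to be below 0.5 cycles, and amplification
efficiencies to lie in 90-110% (recorded as metadata, not used in the math).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

__all__ = [
    "CtRecord",
    "FoldChangeResult",
    "ddct_fold_change",
    "replicate_qc",
    "efficiency_qc",
    "read_ct_table",
]

TEMPLATES = ("apoptotic", "genomic")


@dataclass(frozen=True)
class CtRecord:
    primer_id: str
    template: str  # "apoptotic" or "genomic"
    ct_values: tuple[float, ...]

    def __post_init__(self):
        if self.template not in TEMPLATES:
            raise ValueError(f"template must be one of {TEMPLATES}")
        if len(self.ct_values) < 1:
            raise ValueError("need at least one Ct replicate")
        if any(not math.isfinite(c) or c <= 0 for c in self.ct_values):
            raise ValueError("Ct values must be finite and > 0")

    @property
    def mean_ct(self) -> float:
        return sum(self.ct_values) / len(self.ct_values)

    @property
    def se(self) -> float | None:
        """Standard error of the mean; None for a single replicate."""
        n = len(self.ct_values)
        if n < 2:
            return None
        m = self.mean_ct
        sd = math.sqrt(sum((c - m) ** 2 for c in self.ct_values) / (n - 1))
        return sd / math.sqrt(n)


@dataclass(frozen=True)
class FoldChangeResult:
    primer_id: str
    delta_ct_apoptotic: float
    delta_ct_genomic: float
    ddct: float
    fold_change: float
    fold_low: float
    fold_high: float
    se_flags: dict


def replicate_qc(record: CtRecord, max_se: float = 0.5) -> tuple[bool, float | None]:
    """(passed, SE).  A single replicate cannot be assessed and fails QC."""
    se = record.se
    if se is None:
        return False, None
    return se < max_se, se


def efficiency_qc(efficiency_pct: float, lo: float = 90.0, hi: float = 110.0) -> bool:
    """Amplification-efficiency bound; metadata only, never alters the ddCt."""
    return lo <= efficiency_pct <= hi


def ddct_fold_change(
    target_apop: CtRecord | None,
    target_gen: CtRecord | None,
    negctrl_apop: CtRecord | None,
    negctrl_gen: CtRecord | None,
) -> FoldChangeResult:
    """Double-normalized fold change 2**(-ddCt) from four Ct records.

    The fold-change interval [fold_low, fold_high] propagates technical
    replicate SEs combined in quadrature: 2**(-(ddCt +/- 1.96 * SE_comb)).
    """
    records = {
        "target/apoptotic": target_apop,
        "target/genomic": target_gen,
        "negctrl/apoptotic": negctrl_apop,
        "negctrl/genomic": negctrl_gen,
    }
    for label, rec in records.items():
        if rec is None:
            raise ValueError(f"missing Ct record: {label}")
    d_apop = target_apop.mean_ct - negctrl_apop.mean_ct
    d_gen = target_gen.mean_ct - negctrl_gen.mean_ct
    ddct = d_apop - d_gen
    fold = 2.0 ** (-ddct)

    ses = {label: rec.se for label, rec in records.items()}
    if all(se is not None for se in ses.values()):
        se_comb = math.sqrt(sum(se**2 for se in ses.values()))
    else:
        se_comb = float("nan")
    lo = 2.0 ** (-(ddct + 1.96 * se_comb)) if math.isfinite(se_comb) else float("nan")
    hi = 2.0 ** (-(ddct - 1.96 * se_comb)) if math.isfinite(se_comb) else float("nan")

    se_flags = {
        label: {"se": se, "pass": replicate_qc(rec)[0]}
        for (label, rec), se in zip(records.items(), ses.values())
    }
    return FoldChangeResult(
        primer_id=target_apop.primer_id,
        delta_ct_apoptotic=d_apop,
        delta_ct_genomic=d_gen,
        ddct=ddct,
        fold_change=fold,
        fold_low=lo,
        fold_high=hi,
        se_flags=se_flags,
    )


def read_ct_table(path: str | os.PathLike) -> list[CtRecord]:
    """CSV with columns primer_id, template, then one column per Ct replicate
    (ct1, ct2, ...; blank cells allowed for unequal replicate counts)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"primer_id", "template"}
    if not required.issubset(df.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    ct_cols = [c for c in df.columns if c.lower().startswith("ct")]
    if not ct_cols:
        raise ValueError("Ct table has no ct* replicate columns")
    records = []
    for _, row in df.iterrows():
        cts = tuple(float(row[c]) for c in ct_cols if pd.notna(row[c]))
        records.append(CtRecord(str(row["primer_id"]), str(row["template"]), cts))
    return records


def fold_changes_from_records(
    records: list[CtRecord], negctrl_id: str
) -> list[FoldChangeResult]:
    """Pair every non-control primer with the named negative control and
    compute a FoldChangeResult per primer."""
    by_key = {(r.primer_id, r.template): r for r in records}
    neg_a = by_key.get((negctrl_id, "apoptotic"))
    neg_g = by_key.get((negctrl_id, "genomic"))
    out = []
    for primer in sorted({r.primer_id for r in records} - {negctrl_id}):
        out.append(
            ddct_fold_change(
                by_key.get((primer, "apoptotic")),
                by_key.get((primer, "genomic")),
                neg_a,
                neg_g,
            )
        )
    return out
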