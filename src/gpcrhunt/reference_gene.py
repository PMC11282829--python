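"""Housekeeping reference-gene selection and reference-relative expression.

Independent cohorts differ in sequencing depth and protocol, so absolute RPKM
values are not directly comparable across datasets.  The pipeline therefore
anchors expression to an internal standard: among a panel of candidate
housekeeping genes, the one with the lowest coefficient of variation (CV%)
across a designated (healthy) cohort is selected, and every gene is then
expressed as a percentage of that reference within each sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import ValidationError
from .normalize import UNIT_PCT_REF, ExpressionMatrix

logger = logging.getLogger("gpcrhunt")

#: Default 15-gene candidate panel of widely used housekeeping genes.
#: Overridable wherever a candidate list is accepted.
DEFAULT_HOUSEKEEPING_CANDIDATES = (
    "SDHA", "GAPDH", "ACTB", "B2M", "HPRT1", "TBP", "UBC", "YWHAZ",
    "RPL13A", "PGK1", "PPIA", "GUSB", "TFRC", "HMBS", "RPLP0",
)


@dataclass
class ReferenceGeneReport:
    candidate_cv: dict[str, float]  # CV% per candidate present in the cohort
    selected: str
    cohort_id: str = ""
    skipped: list[str] = field(default_factory=list)  # absent candidates


def cv_percent(values) -> float:
    """Coefficient of variation: sample SD (n-1 denominator) / mean x 100.

    Requires at least two finite values and a strictly positive mean.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValidationError("cv_percent requires at least 2 finite values")
    mean = v.mean()
    if mean <= 0:
        raise ValidationError("cv_percent requires a positive mean")
    return float(v.std(ddof=1) / mean * 100.0)


def select_reference(e: ExpressionMatrix, candidates=DEFAULT_HOUSEKEEPING_CANDIDATES,
                     cohort_id: str = "") -> ReferenceGeneReport:
    """Pick the minimum-CV% candidate; ties broken alphabetically.

    Candidates absent from the matrix are skipped (and reported); at least
    one candidate must be present.
    """
    present = [c for c in candidates if c in e.values.index]
    skipped = [c for c in candidates if c not in e.values.index]
    if skipped:
        logger.warning("reference candidates absent from matrix: %s", skipped)
    if not present:
        raise ValidationError("no reference-gene candidate present in matrix")
    cvs = {c: cv_percent(e.values.loc[c]) for c in present}
    selected = min(sorted(cvs), key=lambda c: cvs[c])  # alphabetic tie-break
    ties = [c for c in cvs if cvs[c] == cvs[selected] and c != selected]
    if ties:
        logger.info("reference CV tie between %s and %s; selected %s",
                    selected, ties, selected)
    logger.info("selected reference gene %s (CV %.2f%%)", selected, cvs[selected])
    return ReferenceGeneReport(candidate_cv=cvs, selected=selected,
                               cohort_id=cohort_id, skipped=skipped)


def relative_to_reference(e: ExpressionMatrix, ref: str) -> ExpressionMatrix:
    """Express every gene as a percentage of the reference gene, per sample.

    value(g, k) = 100 * e(g, k) / e(ref, k).  Samples where the reference is
    zero (or unavailable) are marked entirely unavailable (NaN columns) rather
    than dropped, so downstream fractions can exclude them explicitly.
    """
    if ref not in e.values.index:
        raise ValidationError(f"reference gene {ref!r} absent from matrix")
    refrow = e.values.loc[ref].to_numpy(dtype=float)
    ok = np.isfinite(refrow) & (refrow > 0)
    if not ok.all():
        bad = e.values.columns[~ok].tolist()
        logger.warning("reference gene %s zero/unavailable in samples %s; "
                       "columns marked unavailable", ref, bad)
    vals = e.values.to_numpy(dtype=float).copy()
    out = np.full_like(vals, np.nan)
    out[:, ok] = 100.0 * vals[:, ok] / refrow[ok][None, :]
    df = pd.DataFrame(out, index=e.values.index, columns=e.values.columns)
    return ExpressionMatrix(df, UNIT_PCT_REF,
                            provenance=f"{e.provenance} -> pct_of({ref})")
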