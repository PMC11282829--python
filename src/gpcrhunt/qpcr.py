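"""qPCR relative quantification: ΔCt against a housekeeping reference.

ΔCt(g, s) = Ct(g, s) - Ct(reference, s); each cycle corresponds to one
doubling at 100% amplification efficiency, so a gene with ΔCt = d is
(1 + E)^d times less expressed than the reference (E = efficiency, default
1.0 giving the standard 2^ΔCt).  Target Ct values above the detection limit
(default 35 cycles) are treated as below the limit of detection: the gene is
flagged not detected and its ΔCt / fold values are unavailable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import CtTable, ValidationError

logger = logging.getLogger("gpcrhunt")


@dataclass
class DeltaCtResult:
    """Per sample x gene ΔCt, detection flags and fold-reductions.

    ``invalid_samples`` lists samples whose reference Ct was missing or above
    the detection limit; all their cells are unavailable.
    """

    delta_ct: pd.DataFrame      # genes x samples, NaN where not detected
    detected: pd.DataFrame      # boolean
    fold_reduction: pd.DataFrame  # (1+E)^delta_ct, NaN where not detected
    efficiency: float = 1.0
    reference_gene: str = "SDHA"
    invalid_samples: list[str] = field(default_factory=list)


def fold_reduction(delta_ct, efficiency: float = 1.0):
    """(1 + efficiency) ** delta_ct — how many times less expressed than the
    reference a gene with the given ΔCt is.

    Accepts scalars or arrays; efficiency must lie in (0, 1].
    """
    if not 0 < efficiency <= 1:
        raise ValidationError("amplification efficiency must lie in (0, 1]")
    return (1.0 + efficiency) ** np.asarray(delta_ct, dtype=float) \
        if np.ndim(delta_ct) else float((1.0 + efficiency) ** delta_ct)


def delta_ct(ct: CtTable, efficiency: float = 1.0) -> DeltaCtResult:
    """ΔCt of every gene against the table's reference gene, per sample.

    Samples whose reference Ct is missing or above the detection limit are
    flagged invalid.  Target cells missing or above the limit are flagged not
    detected; the reference gene itself has ΔCt 0 wherever valid.
    """
    if not 0 < efficiency <= 1:
        raise ValidationError("amplification efficiency must lie in (0, 1]")
    ref = ct.reference_gene
    refrow = ct.ct.loc[ref]
    ref_ok = refrow.notna() & (refrow <= ct.detection_limit)
    invalid = ct.ct.columns[~ref_ok].tolist()
    if invalid:
        logger.warning("reference gene %s undetected in samples %s; "
                       "flagged invalid", ref, invalid)
    vals = ct.ct.to_numpy(dtype=float)
    detected = np.isfinite(vals) & (vals <= ct.detection_limit)
    detected[:, ~ref_ok.to_numpy()] = False
    delta = vals - refrow.to_numpy(dtype=float)[None, :]
    delta = np.where(detected, delta, np.nan)
    folds = np.where(detected, (1.0 + efficiency) ** delta, np.nan)
    idx, cols = ct.ct.index, ct.ct.columns
    return DeltaCtResult(
        delta_ct=pd.DataFrame(delta, index=idx, columns=cols),
        detected=pd.DataFrame(detected, index=idx, columns=cols),
        fold_reduction=pd.DataFrame(folds, index=idx, columns=cols),
        efficiency=efficiency,
        reference_gene=ref,
        invalid_samples=invalid,
    )
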