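"""Disease-target set algebra and the DEG threshold filter.

The disease target set is built from three sources: curated databases
(``T_DB``), reference mining (``T_Ref``) and differential expression
(``T_GEO``), combined as ``(T_DB | T_Ref) & T_GEO``.
"""

from __future__ import annotations

import logging
import math

from .io_formats import DegTable, TargetSet, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["filter_degs", "integrate_targets"]


def filter_degs(
    table: DegTable,
    lfc_min: float = 1.5,
    fdr_max: float = 0.05,
    signed: bool = False,
) -> TargetSet:
    """Select differentially expressed genes by strict thresholds.

    A gene passes when ``|log2FC| > lfc_min`` and ``fdr < fdr_max`` (both
    strict).  With ``signed=True`` the literal one-sided reading
    ``log2FC > lfc_min`` is used instead, keeping only up-regulated genes.
    An empty result is allowed (and logged).
    """
    if not (math.isfinite(lfc_min) and math.isfinite(fdr_max)):
        raise ValidationError("thresholds must be finite")
    if lfc_min < 0:
        raise ValidationError(f"lfc_min must be >= 0, got {lfc_min}")
    frame = table.frame
    lfc = frame["log2_fold_change"] if signed else frame["log2_fold_change"].abs()
    mask = (lfc > lfc_min) & (frame["fdr"] < fdr_max)
    genes = frame.loc[mask, "gene"]
    if genes.empty:
        logger.info("DEG filter (|lfc|>%g, fdr<%g) selected no genes", lfc_min, fdr_max)
    return TargetSet(name="deg", source="geo", members=frozenset(genes))


def integrate_targets(
    t_db: TargetSet, t_ref: TargetSet, t_geo: TargetSet
) -> TargetSet:
    """Combine disease targets: ``(T_DB | T_Ref) & T_GEO``.

    The database and reference sets broaden coverage; intersecting with the
    expression-derived set keeps only genes with measured dysregulation in
    the disease tissue.
    """
    members = (t_db.members | t_ref.members) & t_geo.members
    return TargetSet(name="integrated", source="integrated", members=members)
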