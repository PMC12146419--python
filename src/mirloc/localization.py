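"""Propagation of mRNA subcellular annotations onto miRNAs.

A miRNA inherits localisation evidence from the mRNAs it interacts with:
its 7-dim feature row is the degree-normalised mean of its partner mRNAs'
binary localisation rows (a convex combination), or — in ``mode="count"`` —
the raw partner counts per compartment.
"""

from __future__ import annotations

import numpy as np

from .datamodel import AssociationNetwork, DataModelError, FeatureMatrix, LocalizationMatrix


def propagate_mrna_localization(
    assoc: AssociationNetwork, mrna_loc: LocalizationMatrix, mode: str = "mean"
) -> FeatureMatrix:
    """Propagate mRNA localisation labels through the miRNA–mRNA network.

    Parameters
    ----------
    assoc
        Binary miRNA × mRNA association network.
    mrna_loc
        mRNA × 7 binary localisation matrix covering every mRNA in ``assoc``.
    mode
        ``"mean"`` (default) divides each nonzero row by its degree so every
        entry lies in [0, 1]; ``"count"`` keeps raw compartment counts.
    """
    if assoc.entity_kind != "mrna":
        raise DataModelError("propagation requires a miRNA-mRNA network")
    missing = [e for e in assoc.entity_ids if e not in set(mrna_loc.entity_ids)]
    if missing:
        raise DataModelError(f"mRNA {missing[0]!r} has no localisation annotation")
    loc = mrna_loc.align_to(assoc.entity_ids)
    counts = assoc.adjacency.astype(float) @ loc.labels.astype(float)
    if mode == "count":
        values = counts
    elif mode == "mean":
        deg = assoc.adjacency.sum(axis=1, dtype=float)
        values = np.divide(counts, deg[:, None], out=np.zeros_like(counts), where=deg[:, None] > 0)
    else:
        raise ValueError(f"unknown propagation mode {mode!r}")
    return FeatureMatrix(assoc.mirna_ids, values, "mrna_loc")
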