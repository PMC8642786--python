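"""Cross-cohort validation of discovery hits.

A miRNA discovered in one cohort is considered validated when the
second, independent cohort shows a change in the *same direction* with
a nominal two-sided p below ``alpha``.  The asymmetry with the
discovery filter (FDR there, nominal p here) is deliberate: discovery
screens the whole feature space, while validation tests a short,
pre-specified candidate list.

Validation cohorts quantified at the precursor level are first expanded
to mature arm names, each arm inheriting the precursor's statistics
verbatim — a known granularity loss, but the only consistent join when
one precursor measurement has to speak for both arms.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import DETable, NameMap, ValidatedSignature

logger = logging.getLogger(__name__)


def map_precursor_to_mature(validation_de: DETable, name_map: NameMap) -> DETable:
    """Expand precursor-level DE records to mature miRNA names.

    Records whose id is a known precursor are duplicated to all of its
    mature arms with statistics copied verbatim; ids that are already
    mature (or unknown to the map) pass through unchanged.  Unknown ids
    that look like precursors are counted and logged, never dropped.
    """
    rows = []
    index = []
    n_unmapped = 0
    for fid, row in validation_de.frame.iterrows():
        arms = name_map.lookup(str(fid))
        if arms is not None:
            for arm in arms:
                rows.append(row)
                index.append(arm)
        else:
            if not name_map.is_mature(str(fid)) and name_map.precursor_to_mature:
                n_unmapped += 1
            rows.append(row)
            index.append(fid)
    if n_unmapped:
        logger.warning(
            "map_precursor_to_mature: %d ids not present in the name map "
            "were retained under their original names",
            n_unmapped,
        )
    if not rows:
        return DETable(validation_de.frame.copy(), cohort_tag=validation_de.cohort_tag)
    frame = pd.DataFrame(rows, index=pd.Index(index, name=validation_de.frame.index.name))
    dup = frame.index.duplicated()
    if dup.any():
        logger.warning(
            "map_precursor_to_mature: %d duplicate mature ids after expansion; "
            "keeping the first occurrence",
            int(dup.sum()),
        )
        frame = frame.loc[~dup]
    return DETable(frame, cohort_tag=validation_de.cohort_tag)


def filter_validation(
    discovery_hits: DETable, validation_de: DETable, alpha: float = 0.05
) -> ValidatedSignature:
    """Keep discovery hits replicated in the validation cohort.

    A hit is retained when its (mature-mapped) validation record exists,
    has nominal p_value < alpha (strict), and changes in the same
    direction.  Hits absent from the validation table are dropped with
    a logged notice.  The result is ordered by discovery q ascending.
    """
    val = validation_de.frame
    rows = []
    n_absent = 0
    for fid, disc in discovery_hits.frame.iterrows():
        if fid not in val.index:
            n_absent += 1
            continue
        v = val.loc[fid]
        if not (v["p_value"] < alpha):
            continue
        if np.sign(v["log2fc"]) != np.sign(disc["log2fc"]):
            continue
        rows.append(
            {
                "mirna_id": fid,
                "discovery_log2fc": disc["log2fc"],
                "discovery_fold_change": 2.0 ** disc["log2fc"],
                "discovery_q": disc["q_value"],
                "validation_log2fc": v["log2fc"],
                "validation_fold_change": 2.0 ** v["log2fc"],
                "validation_p": v["p_value"],
                "direction": int(np.sign(disc["log2fc"])),
            }
        )
    if n_absent:
        logger.info(
            "filter_validation: %d discovery hits absent from the validation table",
            n_absent,
        )
    frame = pd.DataFrame(
        rows, columns=["mirna_id", *ValidatedSignature.COLUMNS]
    ).set_index("mirna_id")
    frame = frame.sort_values("discovery_q", kind="mergesort")
    sig = ValidatedSignature(frame)
    if sig.n_up_early:
        logger.info(
            "filter_validation: %d validated miRNAs are higher in stage I "
            "(the locally-advanced-overexpressed direction is reported separately)",
            sig.n_up_early,
        )
    return sig
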