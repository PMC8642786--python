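"""A worked example built from published cross-cohort signature values.

The bundled tables hold the printed summary statistics of a 19-miRNA
rectal-cancer staging signature: per mature miRNA the discovery
cohort's fold change (stage II/III over stage I) and FDR-adjusted
q-value, and per precursor the validation cohort's fold change and
nominal p-value (the validation cohort was quantified at the precursor
level, so one precursor value serves both mature arms).  Running the
discovery filter, the precursor-to-mature expansion and the validation
filter over these values reproduces the published signature membership
without any raw data.

Only the printed fold changes and p/q-values are available, so the
per-feature Wald statistics and mean expressions are NaN in the
returned tables; the filters never consult them.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from . import io
from .datatypes import DETable, NameMap

def _data_path(name: str):
    return resources.files("mirstage").joinpath("data", "worked_example", name)


def load_worked_example() -> tuple[DETable, DETable, NameMap]:
    """Load (discovery DE table, precursor-level validation DE table, name map)."""
    with resources.as_file(_data_path("discovery.tsv")) as p:
        disc = pd.read_csv(p, sep="\t")
    with resources.as_file(_data_path("validation_precursor.tsv")) as p:
        val = pd.read_csv(p, sep="\t")
    with resources.as_file(_data_path("name_map.tsv")) as p:
        name_map = io.read_name_map(p)

    disc_frame = pd.DataFrame(
        {
            "log2fc": np.log2(disc["fold_change"].to_numpy()),
            "wald_stat": np.nan,
            "p_value": np.nan,
            "q_value": disc["q_value"].to_numpy(),
            "mean_expression": np.nan,
        },
        index=pd.Index(disc["mirna_id"], name="feature_id"),
    )
    val_frame = pd.DataFrame(
        {
            "log2fc": np.log2(val["fold_change"].to_numpy()),
            "wald_stat": np.nan,
            "p_value": val["p_value"].to_numpy(),
            "q_value": np.nan,
            "mean_expression": np.nan,
        },
        index=pd.Index(val["precursor_id"], name="feature_id"),
    )
    return (
        DETable(disc_frame, cohort_tag="discovery"),
        DETable(val_frame, cohort_tag="validation"),
        name_map,
    )
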