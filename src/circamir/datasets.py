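"""Bundled example data.

``load_top_changed_serum_mirnas`` returns the published summary of the
40 serum miRNAs with at least two-fold expression change between the
before- and after-puberty-onset stages in the chicken study system
(columns: mirna, fold_change, log2_fc as printed at 2 decimals, and
the printed p-value label). It is used by the worked example and by
the screening-arithmetic checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_top_changed_serum_mirnas() -> pd.DataFrame:
    ref = resources.files("circamir") / "data" / "top_changed_serum_mirnas.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
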