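"""Published CVN prostate-cancer performance tables, for summary recomputation.

Two reference tables ship with the package: the seven discovery fingerprints
evaluated on the held-out TCGA-PRAD test split, and the 22
cohort x fingerprint validation rows obtained on independent cohorts by LOO
selection plus bootstrap estimation.  They carry the per-row odds ratio with
CI and p-value, kappa, AUC with p-value and (for discovery) the log-rank
p-value -- exactly the columns whose summary row uses arithmetic means for
values and geometric means for p-values, which
:func:`cvnprog.metrics.summarize_table` reproduces.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_table"]


def load_reference_table(which: str) -> pd.DataFrame:
    """Load the ``"discovery"`` or ``"validation"`` reference table."""
    if which not in ("discovery", "validation"):
        raise ValueError(f"unknown table {which!r}")
    ref = resources.files("cvnprog") / "data" / f"reference_{which}.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
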