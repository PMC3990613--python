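"""Small published tables bundled with the package.

Both tables describe the Nipponbare x 93-11 rice study system and serve as
worked-example inputs:

* :func:`load_ril_qtl_multienv` — per-environment QTL records (marker
  interval, peak, LOD, additive effect ...) for yield-related traits mapped in
  a 266-line RIL population over six field experiments, together with the
  reported per-QTL average LOD score.
* :func:`load_pattern_shares` — reported per-tissue percentages of the AHPL
  and SEF1 F1 expression-pattern categories.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("hetqtl") / "data" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_ril_qtl_multienv() -> pd.DataFrame:
    """Per-environment yield-QTL records for the rice RIL worked example."""
    return _load("ril_qtl_multienv.tsv")


def load_pattern_shares() -> pd.DataFrame:
    """Reported AHPL / SEF1 percentage shares per tissue."""
    return _load("pattern_shares.tsv")
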