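"""Bundled reference tables for the agreement statistics.

Two small CSV fixtures ship with the package:

* ``senior_concordance.csv`` — a 7x7 count matrix of 589 wells double-read
  by two senior immunologists (negative plus six patterns); the standard
  worked example for observed agreement and Cohen's kappa.
* ``cad_pattern_rates.csv`` — published per-class confusion rates (in
  percent) of a HEp-2 CAD against gold-standard pattern labels; its six
  non-empty diagonal rates are the worked example for mean class accuracy.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .evaluation import ConfusionMatrix

__all__ = [
    "load_senior_concordance",
    "load_cad_pattern_rates",
    "cad_diagonal_rates",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("hep2cad.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#", index_col=0)


def load_senior_concordance() -> ConfusionMatrix:
    """The 589-well two-senior-reader concordance count matrix."""
    frame = _read("senior_concordance.csv")
    return ConfusionMatrix(
        classes=tuple(frame.index), counts=frame.to_numpy(dtype=np.int64)
    )


def load_cad_pattern_rates() -> pd.DataFrame:
    """Published CAD-vs-gold per-class pattern rates, in percent."""
    return _read("cad_pattern_rates.csv")


def cad_diagonal_rates(include_empty: bool = False) -> dict[str, float]:
    """Per-class correct rates (percent) from the CAD confusion fixture.

    The ``other`` class had no reference examples; it is excluded unless
    ``include_empty`` is set.
    """
    frame = load_cad_pattern_rates()
    diag = {c: float(frame.loc[c, c]) for c in frame.index}
    if not include_empty:
        diag = {c: v for c, v in diag.items() if c != "other"}
    return diag
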