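"""Bundled validation data.

The package ships the published paired threshold heart rates of the
15-runner incremental-treadmill validation study: for each participant
the gas-exchange second ventilatory threshold HR (reference) and the HR
at which rolling short-term DFA alpha1 reached 0.5 (estimate).  These
printed values are the canonical check for the agreement statistics.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_treadmill_vt2_pairs"]

_VT2_PAIRS = [
    # (participant, VT2 HR bpm, HRVT2 HR bpm)
    (1, 179, 180),
    (2, 183, 183),
    (3, 194, 187),
    (4, 170, 188),
    (5, 148, 160),
    (6, 166, 144),
    (7, 177, 173),
    (8, 182, 176),
    (9, 169, 170),
    (10, 192, 194),
    (11, 160, 143),
    (12, 172, 161),
    (13, 186, 182),
    (14, 180, 171),
    (15, 159, 150),
]


def load_treadmill_vt2_pairs() -> pd.DataFrame:
    """Paired (VT2, HRVT2) heart rates of the treadmill validation cohort.

    Returns
    -------
    DataFrame with columns ``id``, ``ref_hr`` (gas-exchange VT2 HR,
    bpm) and ``est_hr`` (HRVT2, the HR at rolling DFA alpha1 = 0.5,
    bpm), one row per runner (n = 15).
    """
    return pd.DataFrame(_VT2_PAIRS, columns=["id", "ref_hr", "est_hr"])
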