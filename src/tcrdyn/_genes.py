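"""Packaged TRBV/TRBJ gene names with plausible usage weights.

A compact list of common functional human TRB genes. The weights are
order-of-magnitude realistic usage frequencies (dominant TRBV20-1/TRBV5-1,
J2 family used more than J1), not estimates from any dataset; no germline
sequence realism is attempted.
"""
from __future__ import annotations

import numpy as np

TRBV_USAGE: dict[str, float] = {
    "TRBV2": 3.0,
    "TRBV3-1": 1.0,
    "TRBV4-1": 2.0,
    "TRBV4-2": 1.2,
    "TRBV5-1": 6.5,
    "TRBV5-4": 1.5,
    "TRBV5-6": 1.8,
    "TRBV6-1": 2.0,
    "TRBV6-2": 1.5,
    "TRBV6-5": 3.5,
    "TRBV6-6": 1.5,
    "TRBV7-2": 4.5,
    "TRBV7-8": 1.8,
    "TRBV7-9": 3.8,
    "TRBV9": 3.2,
    "TRBV10-3": 1.8,
    "TRBV11-2": 2.5,
    "TRBV12-3": 3.0,
    "TRBV12-4": 1.5,
    "TRBV13": 1.0,
    "TRBV14": 1.5,
    "TRBV15": 1.2,
    "TRBV18": 1.5,
    "TRBV19": 3.5,
    "TRBV20-1": 7.0,
    "TRBV24-1": 1.2,
    "TRBV25-1": 1.5,
    "TRBV27": 2.8,
    "TRBV28": 3.0,
    "TRBV29-1": 2.5,
    "TRBV30": 1.5,
}

TRBJ_USAGE: dict[str, float] = {
    "TRBJ1-1": 6.0,
    "TRBJ1-2": 7.0,
    "TRBJ1-5": 5.0,
    "TRBJ1-6": 3.0,
    "TRBJ2-1": 12.0,
    "TRBJ2-2": 6.0,
    "TRBJ2-3": 9.0,
    "TRBJ2-5": 11.0,
    "TRBJ2-7": 14.0,
}

TRBV_NAMES = tuple(TRBV_USAGE)
TRBJ_NAMES = tuple(TRBJ_USAGE)

TRBV_WEIGHTS = np.asarray(list(TRBV_USAGE.values()), dtype=float)
TRBV_WEIGHTS /= TRBV_WEIGHTS.sum()
TRBJ_WEIGHTS = np.asarray(list(TRBJ_USAGE.values()), dtype=float)
TRBJ_WEIGHTS /= TRBJ_WEIGHTS.sum()
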