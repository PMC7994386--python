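"""Synthetic 96-context signature reference.

A deterministic, self-contained stand-in for a COSMIC-style catalog,
carrying the seven signatures relevant to plasma-cell disorders. Each
profile reproduces the qualitative shape that gives the real signature its
identifiability — SBS1 peaks at N[C>T]G (CpG deamination), SBS2/SBS13 at
T[C>T]N / T[C>G]N (APOBEC), SBS5 is flat and clock-like, SBS18 is C>A
dominated (reactive oxygen), SBS8 broad C>A, SBS9 T-substitution rich
(non-canonical AID) — without copying any published probability table.
Users with access to a real COSMIC TSV can load it via
:func:`mmclock.io_formats.read_signatures` instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contexts import SBS96_CONTEXTS, parse_context
from .io_formats import SignatureMatrix

DEFAULT_MODEL = ("SBS1", "SBS2", "SBS5", "SBS8", "SBS9", "SBS13", "SBS18")

#: clock-like signatures used for absolute timing
CLOCK_SIGNATURES = ("SBS1", "SBS5")

#: APOBEC signatures, eliminated/retained jointly
APOBEC_SIGNATURES = ("SBS2", "SBS13")


def _profile(weight_fn, background: float) -> np.ndarray:
    w = np.array([weight_fn(*parse_context(c)) for c in SBS96_CONTEXTS], dtype=float)
    w = w + background
    return w / w.sum()


def synthetic_signature_reference() -> SignatureMatrix:
    """Deterministic synthetic signature catalog (see module docstring)."""
    profiles = {
        # CpG deamination: C>T with 3' G
        "SBS1": _profile(
            lambda f, r, a, t: 12.0 if (r, a, t) == ("C", "T", "G") else 0.0, 0.05),
        # APOBEC C>T at TpC, strongest with 3' A/T
        "SBS2": _profile(
            lambda f, r, a, t: (8.0 if t in "AT" else 3.0)
            if (f, r, a) == ("T", "C", "T") else 0.0, 0.03),
        # flat clock-like background, mildly T>C enriched
        "SBS5": _profile(
            lambda f, r, a, t: 1.0 + (1.2 if (r, a) == ("T", "C") else 0.0)
            + (0.4 if (r, a) == ("C", "T") else 0.0), 0.0),
        # broad late-replication C>A
        "SBS8": _profile(
            lambda f, r, a, t: 3.0 if r == "C" and a == "A" else 0.3, 0.05),
        # non-canonical AID: sharply T>A dominated at A/T-flanked sites
        "SBS9": _profile(
            lambda f, r, a, t: (8.0 if f in "AT" and t in "AT" else 2.0)
            if (r, a) == ("T", "A")
            else (1.5 if (r, a) == ("T", "C") and f in "AT" else 0.0), 0.02),
        # APOBEC C>G at TpC
        "SBS13": _profile(
            lambda f, r, a, t: (8.0 if t in "AT" else 3.0)
            if (f, r, a) == ("T", "C", "G") else 0.0, 0.03),
        # reactive-oxygen C>A, 3' A/T biased and 5' non-T
        "SBS18": _profile(
            lambda f, r, a, t: (6.0 if t in "AT" and f != "T" else 1.0)
            if (r, a) == ("C", "A") else 0.0, 0.02),
    }
    df = pd.DataFrame(profiles, index=list(SBS96_CONTEXTS))
    return SignatureMatrix(df)
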