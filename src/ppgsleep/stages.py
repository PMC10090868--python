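"""Sleep-stage labels and the two/three/four-class merging schemes.

The canonical per-epoch scoring uses four stages: wake (WAKE), light sleep
(LS), deep sleep (DS) and rapid-eye-movement sleep (REM).  Coarser schemes
merge the sleep stages: the three-class scheme pools LS and DS into NREM,
and the two-class (sleep/wake) scheme pools LS, DS and REM into SLEEP.
"""

from __future__ import annotations

from typing import Iterable, Sequence

WAKE = "WAKE"
LS = "LS"
DS = "DS"
REM = "REM"
NREM = "NREM"
SLEEP = "SLEEP"

FOUR_CLASS: tuple[str, ...] = (WAKE, LS, DS, REM)

#: Classes of each labelling scheme, in canonical (ordinal depth) order.
SCHEME_CLASSES: dict[str, tuple[str, ...]] = {
    "two": (WAKE, SLEEP),
    "three": (WAKE, NREM, REM),
    "four": FOUR_CLASS,
}

#: Default alias table for hypnogram tokens.  AASM exports vary (N1/N2/N3
#: versus the older S1-S4); by convention N1 and N2 map to light sleep and
#: N3 (or S3/S4) to deep sleep.
DEFAULT_ALIASES: dict[str, str] = {
    "W": WAKE, "WAKE": WAKE, "AWAKE": WAKE, "0": WAKE,
    "N1": LS, "N2": LS, "S1": LS, "S2": LS, "LS": LS,
    "N3": DS, "S3": DS, "S4": DS, "DS": DS, "SWS": DS,
    "R": REM, "REM": REM,
    "NREM": NREM, "SLEEP": SLEEP,
}

_THREE_MAP = {WAKE: WAKE, LS: NREM, DS: NREM, REM: REM,
              NREM: NREM, SLEEP: SLEEP}
_TWO_MAP = {WAKE: WAKE, LS: SLEEP, DS: SLEEP, REM: SLEEP,
            NREM: SLEEP, SLEEP: SLEEP}


def merge_stages(labels: Iterable[str], scheme: str) -> list[str]:
    """Remap four-class stage labels onto a coarser scheme.

    ``four`` is the identity; ``three`` merges LS and DS into NREM;
    ``two`` merges LS, DS and REM into SLEEP.  WAKE is always preserved.
    Idempotent: labels already merged for the scheme pass through.
    """
    labels = list(labels)
    if scheme == "four":
        for lab in labels:
            if lab not in FOUR_CLASS:
                raise ValueError(f"label {lab!r} is not a four-class stage")
        return labels
    if scheme == "three":
        mapping = _THREE_MAP
    elif scheme == "two":
        mapping = _TWO_MAP
    else:
        raise ValueError(f"unknown scheme {scheme!r}; expected two/three/four")
    try:
        return [mapping[lab] for lab in labels]
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} is not a stage label") from None


def encode_labels(labels: Sequence[str], scheme: str = "four") -> list[int]:
    """Ordinal encoding of stage labels by sleep depth (WAKE=0 ... REM last).

    Used for the Spearman feature-strength correlation, where the stage
    axis needs a fixed numeric ordering.
    """
    classes = SCHEME_CLASSES[scheme]
    lut = {c: i for i, c in enumerate(classes)}
    try:
        return [lut[lab] for lab in labels]
    except KeyError as exc:
        raise ValueError(
            f"label {exc.args[0]!r} not in scheme {scheme!r}") from None
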