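"""Optional real-data import interfaces.

The analysis chain operates on :class:`~empadecode.containers.EpochSet`
objects; this module reserves the entry point for loading real epoched
recordings from BrainVision triplets.  The synthetic generator covers
every tested code path, so the reader is an interface stub: the
signature is stable, the implementation intentionally absent.
"""

from __future__ import annotations

from pathlib import Path

from .containers import EpochSet

__all__ = ["read_brainvision_epochs"]


def read_brainvision_epochs(
    vhdr_path: str | Path,
    window_ms: tuple[float, float] = (-200.0, 500.0),
) -> EpochSet:
    """Load a BrainVision (.vhdr/.eeg/.vmrk) recording, epoch it around
    stimulus markers and return an :class:`EpochSet`.

    Interface stub — not implemented; real-data import is intentionally
    out of the tested surface.  An implementation would parse the header
    triplet (e.g. via an EEG I/O library), epoch around stimulus-onset
    markers, and populate the per-trial metadata columns expected by the
    decoding and RSA stages.
    """
    raise NotImplementedError(
        "BrainVision import is an interface stub; construct an EpochSet "
        "directly or use the synthetic generator"
    )
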