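"""Binary multi-electrode stimulation patterns.

A stimulation pattern is an ordered tuple of 0/1 indicators, one per
electrode.  With ``n_el`` electrodes there are ``2**n_el - 1`` distinct
non-empty patterns; a five-electrode array therefore yields 31 patterns.

The canonical enumeration order is by pattern id ``1 .. 2**n_el - 1``,
where bit ``i`` (0-based, least significant) of the id drives electrode
``i + 1``.  This ordering is part of the on-disk file contract: the
``pattern_bits`` string written to TSV has electrode 1 leftmost, so
pattern id 1 with three electrodes is ``"100"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

MAX_ELECTRODES = 16  # practical bound on exhaustive pattern enumeration


@dataclass(frozen=True)
class StimulusPattern:
    """One binary stimulation pattern across the electrode array."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.bits:
            raise ValueError("pattern must have at least one electrode")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError(f"pattern bits must be 0 or 1, got {self.bits}")

    @property
    def n_electrodes(self) -> int:
        return len(self.bits)

    @property
    def pattern_id(self) -> int:
        """Integer id: bit i (LSB) of the id is electrode i+1."""
        return sum(b << i for i, b in enumerate(self.bits))

    @property
    def bits_string(self) -> str:
        """Electrode 1 leftmost, e.g. ``"10100"``."""
        return "".join(str(b) for b in self.bits)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=float)

    @classmethod
    def from_id(cls, pattern_id: int, n_el: int) -> "StimulusPattern":
        if not 1 <= pattern_id < 2**n_el:
            raise ValueError(f"pattern id {pattern_id} out of range for {n_el} electrodes")
        return cls(tuple((pattern_id >> i) & 1 for i in range(n_el)))

    @classmethod
    def from_bits_string(cls, s: str) -> "StimulusPattern":
        return cls(tuple(int(c) for c in s))


def enumerate_patterns(n_el: int) -> list[StimulusPattern]:
    """All ``2**n_el - 1`` non-empty binary patterns, in id order.

    Parameters
    ----------
    n_el
        Number of stimulation electrodes (1..16).
    """
    if n_el < 1:
        raise ValueError(f"need at least one electrode, got {n_el}")
    if n_el > MAX_ELECTRODES:
        raise ValueError(f"n_el={n_el} exceeds practical bound {MAX_ELECTRODES}")
    return [StimulusPattern.from_id(pid, n_el) for pid in range(1, 2**n_el)]


def design_matrix(patterns: Sequence[StimulusPattern]) -> np.ndarray:
    """Stack patterns into a (n_patterns, n_electrodes) 0/1 float matrix."""
    return np.stack([p.as_array() for p in patterns])


def iter_singletons(n_el: int) -> Iterator[StimulusPattern]:
    """Single-electrode patterns, electrode 1 first."""
    for i in range(n_el):
        yield StimulusPattern.from_id(1 << i, n_el)
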