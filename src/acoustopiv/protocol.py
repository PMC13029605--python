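"""Acoustic stimulation protocol: ON-OFF scheduling and equal-temperament tones.

The stimulation used throughout the package is a periodic ON-OFF scheme —
1 s of acoustic drive followed by 1 s of rest, repeated over the recording —
whose 2 s period sets a 0.5 Hz fundamental in the velocity response. The
drive tone is specified as a musical pitch in scientific pitch notation
(equal temperament, A4 = 440 Hz); the two standard presets are a G-sharp in
the sub-contra range (:data:`AMP_LOW`, 25.96 Hz) and one four octaves up
(:data:`AMP_HIGH`, 415.30 Hz).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "StimulusProtocol",
    "note_frequency",
    "stimulus_state",
    "modulation_fundamental",
    "amp_low_protocol",
    "amp_high_protocol",
    "protocol_from_preset",
    "AMP_LOW",
    "AMP_HIGH",
]

# Semitone offsets from C within one octave; sharps only (flats resolve via aliases).
_PITCH_CLASSES = {
    "C": 0, "C#": 1, "D": 2, "D#": 3, "E": 4, "F": 5,
    "F#": 6, "G": 7, "G#": 8, "A": 9, "A#": 10, "B": 11,
}
_FLAT_ALIASES = {"DB": "C#", "EB": "D#", "GB": "F#", "AB": "G#", "BB": "A#"}


def note_frequency(pitch_class: str, octave: int, reference_a4: float = 440.0) -> float:
    """Equal-temperament frequency of a pitch in scientific notation.

    Parameters
    ----------
    pitch_class
        One of the 12 chromatic note names, e.g. ``"G#"`` (flats like
        ``"Ab"`` are accepted as aliases).
    octave
        Scientific-pitch octave number, between -1 and 9.
    reference_a4
        Tuning reference for A4 in Hz (default 440).

    Returns
    -------
    float
        ``reference_a4 * 2**(s/12)`` where ``s`` is the semitone offset
        from A4. Full precision is retained; round only for display.
    """
    name = pitch_class.strip().upper().replace("♯", "#").replace("♭", "B")
    name = _FLAT_ALIASES.get(name, name)
    if name not in _PITCH_CLASSES:
        raise ValueError(f"unknown pitch class {pitch_class!r}")
    if not (-1 <= int(octave) <= 9):
        raise ValueError(f"octave {octave} outside [-1, 9]")
    # Semitones from A4: octave distance anchored at C, minus A's offset of 9.
    semitones = (int(octave) - 4) * 12 + (_PITCH_CLASSES[name] - 9)
    return float(reference_a4) * 2.0 ** (semitones / 12.0)


#: Drive-tone presets: G#0 (25.96 Hz) and G#4 (415.30 Hz).
AMP_LOW: float = note_frequency("G#", 0)
AMP_HIGH: float = note_frequency("G#", 4)


@dataclass(frozen=True)
class StimulusProtocol:
    """Periodic ON-OFF stimulation schedule with a carrier tone.

    The schedule starts in the ON phase at t = 0 and boundary instants
    belong to the phase they open (half-open intervals).
    """

    on_duration: float = 1.0
    off_duration: float = 1.0
    total_duration: float = 60.0
    tone_frequency: float = AMP_LOW
    label: str = ""

    def __post_init__(self) -> None:
        if self.on_duration <= 0:
            raise ValueError("on_duration must be > 0")
        if self.off_duration < 0:
            raise ValueError("off_duration must be >= 0")
        if self.total_duration <= 0:
            raise ValueError("total_duration must be > 0")
        if self.total_duration < self.on_duration + self.off_duration:
            raise ValueError("total_duration shorter than one ON-OFF period")
        if self.tone_frequency <= 0:
            raise ValueError("tone_frequency must be > 0")

    @property
    def period(self) -> float:
        """Modulation period in seconds (ON plus OFF)."""
        return self.on_duration + self.off_duration

    def state(self, t):
        """Vectorized :func:`stimulus_state`; returns boolean ON mask."""
        import numpy as np

        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t >= self.total_duration):
            raise ValueError("t outside [0, total_duration)")
        return np.mod(t, self.period) < self.on_duration

    def to_dict(self) -> dict:
        return {
            "on_s": self.on_duration,
            "off_s": self.off_duration,
            "total_s": self.total_duration,
            "tone": {"hz": self.tone_frequency},
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        tone = d.get("tone", {})
        if "hz" in tone:
            hz = float(tone["hz"])
        elif "note" in tone:
            hz = note_frequency(tone["note"], int(tone["octave"]))
        else:
            raise ValueError("tone must give either {hz} or {note, octave}")
        return cls(
            on_duration=float(d["on_s"]),
            off_duration=float(d["off_s"]),
            total_duration=float(d.get("total_s", 60.0)),
            tone_frequency=hz,
            label=str(d.get("label", "")),
        )

    def save(self, path: Union[str, Path]) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "StimulusProtocol":
        path = Path(path)
        data = yaml.safe_load(path.read_text())  # YAML is a JSON superset
        return cls.from_dict(data)


def stimulus_state(protocol: StimulusProtocol, t: float) -> bool:
    """True if the stimulus is ON at time ``t`` (seconds from record start).

    ON iff ``t mod period < on_duration``; raises for t outside
    ``[0, total_duration)``.
    """
    if not (0 <= t < protocol.total_duration):
        raise ValueError(f"t={t} outside [0, {protocol.total_duration})")
    return (t % protocol.period) < protocol.on_duration


def modulation_fundamental(protocol: StimulusProtocol) -> float:
    """Fundamental modulation frequency in Hz, ``1 / (on + off)``."""
    if protocol.period <= 0:
        raise ValueError("zero modulation period")
    return 1.0 / protocol.period


def amp_low_protocol(total_duration: float = 60.0) -> StimulusProtocol:
    """1 s ON / 1 s OFF protocol driven at G#0 (25.96 Hz)."""
    return StimulusProtocol(
        1.0, 1.0, total_duration, AMP_LOW, label="AMP 1st octave"
    )


def amp_high_protocol(total_duration: float = 60.0) -> StimulusProtocol:
    """1 s ON / 1 s OFF protocol driven at G#4 (415.30 Hz)."""
    return StimulusProtocol(
        1.0, 1.0, total_duration, AMP_HIGH, label="AMP 4th octave"
    )


def protocol_from_preset(name: str, total_duration: float = 60.0):
    """Resolve a preset name to a protocol; ``"no-amp"`` maps to ``None``."""
    key = name.strip().lower().replace("_", "-")
    if key in ("no-amp", "none", "control"):
        return None
    if key == "amp-low":
        return amp_low_protocol(total_duration)
    if key == "amp-high":
        return amp_high_protocol(total_duration)
    raise ValueError(f"unknown protocol preset {name!r}")
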