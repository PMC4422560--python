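"""Plate-layout configuration and table I/O helpers.

A plate layout is a YAML (or JSON) mapping with the schema::

    pixel_size_um: 2.5          # μm per pixel
    frame_interval_s: 30.0
    uncage_frame: 17            # 0-based index of the first in-gradient frame
    gradient_center_px: [639.5, 511.5]   # optional; default image center
    channels:                   # channel label -> population role
      CFP: control
      RFP: experimental
    wells:                      # well id -> condition metadata
      A1:
        condition: FPR1
        dose_nM: 100            # free-form extras are carried through

Only ``wells`` and the channel→population mapping are required for screen
analysis; the acquisition keys override the defaults used by the imaging
and statistics stages.
"""

from __future__ import annotations

from pathlib import Path

import yaml

REQUIRED_KEYS = {"wells", "channels"}

DEFAULTS = {
    "pixel_size_um": 2.5,
    "frame_interval_s": 30.0,
    "uncage_frame": 17,
    "gradient_center_px": None,
}


def load_layout(path: str | Path) -> dict:
    """Load and validate a plate layout from YAML/JSON."""
    with open(path) as fh:
        layout = yaml.safe_load(fh)
    if not isinstance(layout, dict):
        raise ValueError("layout must be a mapping")
    missing = REQUIRED_KEYS - set(layout)
    if missing:
        raise ValueError(f"layout missing required keys {sorted(missing)}")
    for well, meta in layout["wells"].items():
        if not isinstance(meta, dict) or "condition" not in meta:
            raise ValueError(f"well {well!r} must map to a dict with a 'condition'")
    roles = set(layout["channels"].values())
    if not roles <= {"experimental", "control"}:
        raise ValueError("channel roles must be 'experimental' or 'control'")
    out = dict(DEFAULTS)
    out.update(layout)
    return out
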