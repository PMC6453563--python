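"""JSON/CSV/TIFF I/O helpers shared across the pipeline."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def save_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, cls=_NumpyEncoder, indent=2)


def load_json(path):
    with open(path) as fh:
        return json.load(fh)


def save_mask_tiff(mask, path) -> None:
    """Write a boolean mask as an 8-bit TIFF (0/255)."""
    import tifffile

    arr = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    tifffile.imwrite(path, (arr.astype(np.uint8)) * 255)
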