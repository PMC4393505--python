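"""Reading and writing 8-bit grayscale rasters (PGM P2/P5, PNG) and JSON-lines cohorts."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
from PIL import Image


def read_gray(path: str | Path) -> np.ndarray:
    """Read a grayscale image as a 2-D uint8 array (rows top->bottom)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.uint8)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image")
    return arr


def write_gray(arr: np.ndarray, path: str | Path) -> None:
    """Write a 2-D uint8 array; format chosen by extension (.pgm -> P5, .png -> PNG)."""
    a = np.asarray(arr)
    if a.dtype == bool:
        a = a.astype(np.uint8) * 255
    if a.dtype != np.uint8:
        a = np.clip(np.rint(a), 0, 255).astype(np.uint8)
    Image.fromarray(a, mode="L").save(path)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    write_gray(np.asarray(mask, dtype=bool), path)


def read_mask(path: str | Path) -> np.ndarray:
    return read_gray(path) > 127


# ----- transaction cohorts: one JSON object per line -----

def _item_to_json(item):
    return item


def write_cohort(transactions: Iterable[tuple[frozenset, frozenset]], path: str | Path) -> None:
    """One transaction per line: {"items": sorted list, "keywords": sorted list}."""
    with open(path, "w") as fh:
        for items, keywords in transactions:
            fh.write(json.dumps({
                "items": sorted(items, key=str),
                "keywords": sorted(keywords, key=str),
            }) + "\n")


def read_cohort(path: str | Path) -> list[tuple[frozenset, frozenset]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                items = frozenset(_as_item(x) for x in rec["items"])
                keywords = frozenset(str(k) for k in rec["keywords"])
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed transaction line: {exc}") from exc
            out.append((items, keywords))
    return out


def _as_item(x):
    # JSON round-trips ints and strings; lists encode (name, interval) feature items
    if isinstance(x, list):
        return tuple(x)
    return x
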