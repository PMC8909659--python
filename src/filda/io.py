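"""CSV spectra I/O and JSON model serialization.

Spectra CSV layout (one header row, one row per sample)::

    sample_id,label,900.0,903.5,...,1700.0
    s0001,0,0.612,0.618,...

The wavelength columns must be numeric and strictly ascending.  Reading is
strict: malformed cells are reported with their line number, and a
descending wavelength header names the first offending pair.

Fitted pipelines serialize to a flat, versioned JSON document holding the
preprocessing state, the PCA model, the discriminant projection, the fuzzy
parameters (when present) and the KNN reference set.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .spectra import SpectraSet, ValidationError

__all__ = [
    "read_spectra_csv",
    "write_spectra_csv",
    "save_model_json",
    "load_model_json",
    "MODEL_SCHEMA_VERSION",
]

MODEL_SCHEMA_VERSION = 1


class SpectraParseError(ValidationError):
    """CSV did not match the documented spectra layout."""


def write_spectra_csv(s: SpectraSet, path: Union[str, Path]) -> None:
    """Write a SpectraSet in the documented CSV layout (full float precision)."""
    df = pd.DataFrame(s.absorbance, columns=[repr(float(w)) for w in s.wavelengths])
    df.insert(0, "label", s.labels)
    df.insert(0, "sample_id", s.sample_ids)
    df.to_csv(path, index=False)


def read_spectra_csv(path: Union[str, Path]) -> SpectraSet:
    """Parse a spectra CSV, validating layout, types and wavelength order."""
    path = Path(path)
    if not path.exists():
        raise SpectraParseError(f"no such file: {path}")
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    cols = list(df.columns)
    if cols[:2] != ["sample_id", "label"]:
        raise SpectraParseError(
            f"{path}: header must start with 'sample_id,label', got {cols[:2]}"
        )
    if len(cols) < 3:
        raise SpectraParseError(f"{path}: no wavelength columns found")
    try:
        wavelengths = np.array([float(c) for c in cols[2:]])
    except ValueError as exc:
        raise SpectraParseError(f"{path}: non-numeric wavelength column header: {exc}") from exc
    diffs = np.diff(wavelengths)
    if wavelengths.size > 1 and not np.all(diffs > 0):
        i = int(np.flatnonzero(diffs <= 0)[0])
        raise SpectraParseError(
            f"{path}: wavelength columns must be strictly ascending; first offending "
            f"pair ({wavelengths[i]:g}, {wavelengths[i + 1]:g})"
        )

    labels = pd.to_numeric(df["label"], errors="coerce")
    bad = labels.index[labels.isna()]
    if len(bad):
        # +2: one for the header row, one for 0-based indexing
        raise SpectraParseError(f"{path}: non-numeric label at line {bad[0] + 2}")

    absorbance = np.empty((len(df), wavelengths.size))
    for j, col in enumerate(cols[2:]):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        if df[col].isna().any():
            bad = bad.union(vals.index[df[col].isna()])
        if len(bad):
            raise SpectraParseError(
                f"{path}: non-numeric absorbance in column {col!r} at line {bad[0] + 2}"
            )
        absorbance[:, j] = vals.to_numpy()

    return SpectraSet(
        wavelengths=wavelengths,
        absorbance=absorbance,
        labels=labels.astype(int).to_numpy(),
        sample_ids=df["sample_id"].tolist(),
    )


# ----------------------------------------------------------------------
# model JSON
# ----------------------------------------------------------------------

def _encode(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    return obj


def save_model_json(document: dict, path: Union[str, Path]) -> None:
    """Write a model document as versioned JSON (sorted keys, full precision)."""
    doc = dict(document)
    doc.setdefault("schema_version", MODEL_SCHEMA_VERSION)
    Path(path).write_text(json.dumps(_encode(doc), sort_keys=True, indent=1))


def load_model_json(path: Union[str, Path]) -> dict:
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValidationError(
            f"unsupported model schema version {version!r} (expected {MODEL_SCHEMA_VERSION})"
        )
    return doc
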