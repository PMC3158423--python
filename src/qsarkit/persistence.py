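"""Durable model bundles.

A trained model is saved as a single zip archive holding a human-readable
manifest (family, hyper-parameters, schema, provenance), the preprocessing
state (imputation fill values, scaling bounds) as JSON, the fitted predictor
state, and — when present — the applicability-domain calibration. Loading
reproduces predictions bit-exactly with no retraining, so saved models are
usable from other environments; the readable manifest keeps the bundle
inspectable, supporting the transparency expected of regulatory QSAR models.
"""

from __future__ import annotations

import json
import pickle
import zipfile
from datetime import datetime, timezone
from pathlib import Path

from .domain import MahalanobisDomain
from .exceptions import BundleIntegrityError, BundleVersionError
from .learners import BaseLearner

FORMAT_VERSION = 1
_REQUIRED = ("manifest.json", "preprocessing.json", "predictor.pkl")


def _jsonable(obj):
    try:
        json.dumps(obj)
        return obj
    except TypeError:
        return repr(obj)


def save(
    model: BaseLearner,
    path: str | Path,
    domain: MahalanobisDomain | None = None,
    descriptor_backend: str | None = None,
    seed: int | None = None,
) -> Path:
    """Write a self-contained bundle; returns the path."""
    path = Path(path)
    if domain is None:
        domain = getattr(model, "domain_", None)
    manifest = {
        "format_version": FORMAT_VERSION,
        "family": getattr(model, "family", type(model).__name__),
        "task": model.task_,
        "classes": list(model.classes_) if model.classes_ else None,
        "schema": [v.to_dict() for v in model.schema_],
        "params": {k: _jsonable(v) for k, v in model.get_params(deep=False).items()},
        "descriptor_backend": descriptor_backend,
        "provenance": {
            "seed": seed if seed is not None else getattr(model, "random_state", None),
            "created": datetime.now(timezone.utc).isoformat(),
            "writer": "qsarkit",
        },
        "has_domain": domain is not None,
    }
    imputer = getattr(model, "imputer_", None)  # consensus: state lives in members
    scaler = getattr(model, "scaler_", None)
    preprocessing = {
        "imputation": imputer.to_dict() if imputer is not None else None,
        "scaling": scaler.to_dict() if scaler is not None else None,
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))
        zf.writestr("preprocessing.json", json.dumps(preprocessing, indent=1))
        zf.writestr("predictor.pkl", pickle.dumps(model, protocol=4))
        if domain is not None:
            zf.writestr("domain.json", json.dumps(domain.to_dict()))
    return path


def inspect(path: str | Path) -> dict:
    """Read only the manifest of a bundle."""
    with _open(path) as zf:
        return json.loads(zf.read("manifest.json"))


def _open(path) -> zipfile.ZipFile:
    try:
        zf = zipfile.ZipFile(Path(path), "r")
    except (zipfile.BadZipFile, FileNotFoundError, OSError) as exc:
        raise BundleIntegrityError(f"cannot open bundle {path}: {exc}") from exc
    bad = zf.testzip()
    if bad is not None:
        raise BundleIntegrityError(f"bundle member {bad!r} is corrupt")
    missing = [m for m in _REQUIRED if m not in zf.namelist()]
    if missing:
        raise BundleIntegrityError(f"bundle is missing member(s): {missing}")
    return zf


def load(path: str | Path) -> BaseLearner:
    """Load a bundle back into a ready-to-predict model.

    A calibrated applicability domain, when bundled, is reattached as
    ``model.domain_``. Bundles written by a newer format version fail
    cleanly rather than mis-loading.
    """
    with _open(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        version = int(manifest.get("format_version", 0))
        if version > FORMAT_VERSION:
            raise BundleVersionError(
                f"bundle format v{version} is newer than supported v{FORMAT_VERSION}"
            )
        try:
            model = pickle.loads(zf.read("predictor.pkl"))
        except Exception as exc:
            raise BundleIntegrityError(f"predictor state unreadable: {exc}") from exc
        if "domain.json" in zf.namelist():
            model.domain_ = MahalanobisDomain.from_dict(json.loads(zf.read("domain.json")))
    return model
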