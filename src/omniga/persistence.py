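"""Model artifact save/load.

The artifact is a joblib-pickled, versioned container holding the fitted
preprocessing (normalizer, feature subset), the chosen prediction scheme and
all fitted components, plus provenance (seed, add-on configuration, GA
configuration).  A saved-then-loaded artifact reproduces predictions
bit-identically on the same input.
"""

from __future__ import annotations

from pathlib import Path

import joblib

from .framework import FrameworkModel

ARTIFACT_VERSION = 1

__all__ = ["ARTIFACT_VERSION", "save_model", "load_model"]


def save_model(model: FrameworkModel, path: str, provenance: dict | None = None) -> None:
    payload = {
        "format_version": ARTIFACT_VERSION,
        "model": model,
        "provenance": provenance or {},
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(payload, path)


def load_model(path: str) -> tuple[FrameworkModel, dict]:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != ARTIFACT_VERSION:
        raise ValueError(
            f"unsupported artifact version {version!r} "
            f"(this build reads version {ARTIFACT_VERSION})"
        )
    return payload["model"], payload.get("provenance", {})
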