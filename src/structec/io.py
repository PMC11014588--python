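"""Delimited-text and structured-text I/O.

Matrices travel as tab-separated text with a header row of region
labels and one row per region; time series as tab-separated text with a
header row of region labels and one row per time point.  Floats are
written at 15 significant digits.  Cross-spectra, posteriors and
experiment reports are JSON documents (frequencies in Hz; complex
matrices split into real and imaginary parts at 17 significant digits,
which round-trips float64 exactly).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, MisalignedSubjectsError
from .forward import CrossSpectra, FrequencyGrid
from .gaussian import GaussianDensity
from .invert import DCMPosterior
from .peb import StructuralConnectivity

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_timeseries",
    "read_timeseries",
    "read_structural",
    "write_csd",
    "read_csd",
    "write_posterior",
    "read_posterior",
    "write_report",
]

FLOAT_FMT = "%.15g"


def write_matrix(path: str | Path, weights: np.ndarray, labels: list[str] | tuple[str, ...]) -> None:
    df = pd.DataFrame(np.asarray(weights, dtype=float), columns=list(labels))
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def read_structural(path: str | Path, expected_labels: list[str] | None = None) -> StructuralConnectivity:
    w, labels = read_matrix(path)
    if expected_labels is not None and list(labels) != list(expected_labels):
        missing = sorted(set(expected_labels) - set(labels))
        extra = sorted(set(labels) - set(expected_labels))
        raise MisalignedSubjectsError(
            f"structural labels do not match time-series labels (missing: {missing}, unexpected: {extra})"
        )
    return StructuralConnectivity(w, tuple(labels))


write_timeseries = write_matrix


def read_timeseries(path: str | Path) -> tuple[np.ndarray, list[str]]:
    return read_matrix(path)


def write_csd(path: str | Path, csd: CrossSpectra) -> None:
    doc = {
        "frequencies_hz": [float(f) for f in csd.grid.hz],
        "real": [np.real(m).tolist() for m in csd.matrices],
        "imag": [np.imag(m).tolist() for m in csd.matrices],
    }
    Path(path).write_text(json.dumps(doc))


def read_csd(path: str | Path) -> CrossSpectra:
    doc = json.loads(Path(path).read_text())
    grid = FrequencyGrid(np.array(doc["frequencies_hz"], dtype=float))
    m = np.array(doc["real"], dtype=float) + 1j * np.array(doc["imag"], dtype=float)
    return CrossSpectra(grid, m)


def write_posterior(path: str | Path, post: DCMPosterior) -> None:
    doc = {
        "names": list(post.posterior.names),
        "mean": post.posterior.mean.tolist(),
        "cov": post.posterior.cov.tolist(),
        "free_energy": post.free_energy,
        "iterations": post.iterations,
        "converged": post.converged,
        "noise_log_precision": post.noise_log_precision,
        "scale_factor": post.scale_factor,
    }
    Path(path).write_text(json.dumps(doc))


def read_posterior(path: str | Path) -> DCMPosterior:
    doc = json.loads(Path(path).read_text())
    q = GaussianDensity(np.array(doc["mean"]), np.array(doc["cov"]), tuple(doc["names"]))
    return DCMPosterior(
        q,
        float(doc["free_energy"]),
        int(doc["iterations"]),
        bool(doc["converged"]),
        float(doc["noise_log_precision"]),
        float(doc.get("scale_factor", 1.0)),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_report(path: str | Path, report: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(_jsonable(report), indent=1))


def load_yaml_config(path: str | Path) -> dict:
    import yaml

    doc = yaml.safe_load(Path(path).read_text())
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping")
    return doc
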