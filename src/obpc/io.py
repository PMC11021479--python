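"""Configuration, file formats, seeds, and provenance.

Response tensors live in HDF5 (``amplitudes``, ``blank_amplitudes``,
``roi_ids`` plus a ``population_label`` attribute) with a JSON sidecar
(``<file>.panel.json``) describing the stimulus panel.  Analysis outputs are
plain CSV.  Run configurations are YAML or JSON with strict key validation;
every CLI run writes a provenance record (config + seed + package version)
sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .pipeline import (ClassifiedResponses, OverlapComparison, ResponseTensor,
                       SimilarityMatrix, SparsenessReport, Stimulus,
                       StimulusPanel)

__all__ = [
    "ConfigError",
    "FormatError",
    "RunConfig",
    "DEFAULT_CONFIG",
    "load_config",
    "save_config",
    "seed_streams",
    "configure_logging",
    "write_tensor",
    "read_tensor",
    "panel_to_json",
    "panel_from_json",
    "classified_frame",
    "sparseness_frame",
    "similarity_frame",
    "overlap_frame",
    "write_provenance",
]

logger = logging.getLogger("obpc")


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


class FormatError(ValueError):
    """A file does not match the documented on-disk schema."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out": None,
    "log_level": "INFO",
    "circuit": {
        "n_glomeruli": 400,
        "n_cortical": 5000,
        "log_affinity_sd": 3.0,
        "activation_prob": 0.2,
        "density": 0.1,
        "scale": 0.5,
        "w_inh": 1.0,
        "beta": 2.0,
        "v_thr": 2000.0,
        "tau": 1.0,
        "dt": 0.01,
        "duration": 20.0,
        "heterogeneous": False,
        "n_interneurons": 500,
        "jitter_sd": 0.2,
    },
    "osn": {
        "n_rois": 400,
        "component_response_prob": 0.12,
        "drive_logmean": 0.5,
        "drive_logsd": 1.0,
        "mixture_rule": "additive_saturating",
        "hill_slope": 2.0,
        "suppressed_fraction": 0.1,
        "amp_scale": 1.0,
        "trial_noise_sd": 0.12,
        "n_trials": 3,
        "n_blank_trials": 6,
    },
    "bouton": {
        "n_rois": 800,
        "density": 0.278,
        "enhanced_fraction": 0.446,
        "amp_logmean": -0.5,
        "amp_logsd": 0.5,
        "amp_scale": 1.0,
        "trial_noise_sd": 0.39,
        "decorrelate": True,
        "circuit_mode": False,
        "mixture_concentration": 1.0,
        "n_trials": 3,
        "n_blank_trials": 6,
    },
    "analysis": {
        "n_sd": 3.0,
        "threshold_mode": "per_roi",
        "overlap_threshold": 0.75,
        "overlap_method": "max",
        "overlap_sizes": [8, 12],
    },
}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with all defaults filled in."""

    seed: int = 0
    out: str | None = None
    log_level: str = "INFO"
    circuit: dict = dataclasses.field(default_factory=dict)
    osn: dict = dataclasses.field(default_factory=dict)
    bouton: dict = dataclasses.field(default_factory=dict)
    analysis: dict = dataclasses.field(default_factory=dict)
    command: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("command")
        return d


def _merge_section(name: str, defaults: dict, user: dict) -> dict:
    if not isinstance(user, dict):
        raise ConfigError(f"section '{name}' must be a mapping")
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown key(s) in '{name}': {sorted(unknown)}")
    return {**defaults, **user}


def make_config(data: dict | None = None, command: str | None = None) -> RunConfig:
    """Build a RunConfig from a (possibly partial) dict, rejecting unknown keys."""
    data = dict(data or {})
    unknown = set(data) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    sections = {name: _merge_section(name, DEFAULT_CONFIG[name], data.get(name, {}))
                for name in ("circuit", "osn", "bouton", "analysis")}
    seed = data.get("seed", DEFAULT_CONFIG["seed"])
    if not isinstance(seed, (int, np.integer)) or isinstance(seed, bool):
        raise ConfigError("'seed' must be an integer")
    return RunConfig(seed=int(seed), out=data.get("out"),
                     log_level=str(data.get("log_level", "INFO")),
                     command=command, **sections)


def load_config(path, command: str | None = None) -> RunConfig:
    """Load and validate a YAML or JSON configuration file."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    try:
        data = yaml.safe_load(p.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {p}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"config root in {p} must be a mapping")
    return make_config(data, command=command)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def seed_streams(seed: int, names: tuple[str, ...]) -> dict:
    """Expand one global seed into named independent sub-seeds (< 2^31)."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: int(c.generate_state(1)[0] % 2**31)
            for name, c in zip(names, children)}


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(level=getattr(logging, level.upper(), logging.INFO),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")


# ---------------------------------------------------------------------------
# Stimulus panel JSON
# ---------------------------------------------------------------------------

def panel_to_json(panel: StimulusPanel) -> list:
    return [{
        "id": s.id,
        "kind": s.kind,
        "components": sorted(s.components),
        "n_components": s.n_components,
        "concentration_level": s.concentration_level,
        "concentration": s.concentration,
    } for s in panel]


def panel_from_json(data: list) -> StimulusPanel:
    stimuli = []
    for entry in data:
        try:
            stimuli.append(Stimulus(
                id=entry["id"], kind=entry["kind"],
                components=frozenset(entry["components"]),
                concentration_level=entry.get("concentration_level"),
                concentration=entry.get("concentration")))
        except KeyError as exc:
            raise FormatError(f"panel entry missing key {exc}") from exc
    return StimulusPanel(tuple(stimuli))


# ---------------------------------------------------------------------------
# Tensor HDF5 container
# ---------------------------------------------------------------------------

def _sidecar(path) -> Path:
    return Path(str(path) + ".panel.json")


def write_tensor(tensor: ResponseTensor, path) -> None:
    """Write amplitudes + blanks to HDF5 and the panel to a JSON sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("amplitudes", data=tensor.amplitudes)
        f.create_dataset("blank_amplitudes", data=tensor.blank_amplitudes)
        f.create_dataset("roi_ids",
                         data=np.array(tensor.roi_ids, dtype=h5py.string_dtype()))
        f.attrs["population_label"] = tensor.population_label
        f.attrs["format_version"] = 1
    _sidecar(path).write_text(json.dumps(panel_to_json(tensor.panel), indent=1))


def read_tensor(path) -> ResponseTensor:
    """Read a tensor written by :func:`write_tensor` (lossless round-trip)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"tensor file not found: {path}")
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FormatError(f"panel sidecar not found: {sidecar}")
    with h5py.File(path, "r") as f:
        for name in ("amplitudes", "blank_amplitudes", "roi_ids"):
            if name not in f:
                raise FormatError(f"dataset '{name}' missing from {path}")
        amplitudes = f["amplitudes"][()]
        blanks = f["blank_amplitudes"][()]
        roi_ids = tuple(s.decode() if isinstance(s, bytes) else str(s)
                        for s in f["roi_ids"][()])
        label = f.attrs.get("population_label", "OSN")
    panel = panel_from_json(json.loads(sidecar.read_text()))
    if amplitudes.ndim != 3 or amplitudes.shape[1] != len(panel):
        raise FormatError("amplitudes shape does not match the panel sidecar")
    return ResponseTensor(amplitudes, blanks, panel, roi_ids=roi_ids,
                          population_label=str(label))


# ---------------------------------------------------------------------------
# CSV exports
# ---------------------------------------------------------------------------

def classified_frame(tensor: ResponseTensor,
                     classified: ClassifiedResponses) -> pd.DataFrame:
    """Long table with one row per ROI-stimulus pair."""
    names = classified.label_names()
    rows = []
    for i, roi in enumerate(tensor.roi_ids):
        for j, sid in enumerate(tensor.panel.ids):
            rows.append((roi, sid, names[i, j], classified.trial_mean[i, j],
                         classified.thresholds[i, 0], classified.thresholds[i, 1]))
    return pd.DataFrame(rows, columns=["roi_id", "stimulus_id", "label",
                                       "trial_mean", "threshold_low",
                                       "threshold_high"])


def sparseness_frame(report: SparsenessReport, tensor: ResponseTensor) -> pd.DataFrame:
    """Per-stimulus PS and per-ROI LS, long format."""
    ps = pd.DataFrame({"metric": "population_sparseness",
                       "unit": tensor.panel.ids,
                       "value": report.population_sparseness})
    kept = [r for r, keep in zip(tensor.roi_ids, report.roi_mask) if keep]
    ls = pd.DataFrame({"metric": "lifetime_sparseness", "unit": kept,
                       "value": report.lifetime_sparseness})
    return pd.concat([ps, ls], ignore_index=True)


def similarity_frame(matrix: SimilarityMatrix) -> pd.DataFrame:
    t = matrix.trials_per_stimulus
    labels = [f"{sid}#t{k + 1}" if t > 1 else sid
              for sid in matrix.stimulus_ids for k in range(t)]
    df = pd.DataFrame(matrix.entries, index=labels, columns=labels)
    df.index.name = "stimulus"
    return df


def overlap_frame(comparison: OverlapComparison) -> pd.DataFrame:
    rows = [("high", r) for r in comparison.high] + \
           [("low", r) for r in comparison.low]
    return pd.DataFrame(rows, columns=["overlap_group", "correlation"])


def write_provenance(out_dir, command: str, config: RunConfig,
                     extra: dict | None = None) -> Path:
    """Record everything needed to reproduce a run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "package": "obpc",
        "version": __version__,
        "command": command,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": config.seed,
        "config": config.to_dict(),
    }
    if extra:
        record.update(extra)
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=1, default=str))
    return path
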