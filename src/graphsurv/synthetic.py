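"""Synthetic cohorts with a planted prognostic tissue region.

Each synthetic "slide" is a full rectangular patch grid carrying Gaussian
node features. A random axis-aligned rectangle — the planted high-risk
region — has its feature mean shifted by ``effect_size``, standing in for a
histologic pattern associated with outcome. The fraction of the grid the
rectangle covers (the *prevalence*) drives everything downstream:

* gene-signature values are noisy linear readouts of prevalence
  (``prevalence * w_m + N(0, 1)`` per entry, with a fixed per-signature
  loading ``w_m``), emulating bulk expression correlated with the amount of
  the high-risk tissue component;
* survival follows a discrete-time hazard ``h = hazard_base +
  hazard_slope * prevalence`` per yearly bin: the event bin is geometric in
  ``h``, the continuous time uniform within its bin, and a fraction
  ``censor_rate`` of subjects is right-censored at a uniform earlier time.

Every sample draws from its own RNG stream (``seed + index``) so growing a
cohort never reshuffles earlier samples, and regeneration with the same
config is bit-identical. The planted rectangle doubles as the ground-truth
annotation mask for saliency evaluation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .graphs import ImagingGraph, build_adjacency, save_graph

logger = logging.getLogger(__name__)

__all__ = ["SyntheticCohortConfig", "SyntheticSample", "generate_cohort",
           "write_cohort", "read_cohort"]

_MAX_GEOMETRIC_BINS = 500  # hard cap on the geometric draw (p >= hazard_base)


@dataclass
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort (defaults = demo cohort)."""

    n_samples: int = 200
    grid_height: int = 16
    grid_width: int = 16
    feature_dim: int = 32
    n_signatures: int = 5
    region_fraction_range: tuple[float, float] = (0.05, 0.9)
    effect_size: float = 2.0
    hazard_base: float = 0.1
    hazard_slope: float = 0.5
    censor_rate: float = 0.2
    seed: int = 7
    signature_length: int = 8
    bin_width_days: float = 365.0

    def validate(self) -> None:
        for name in ("n_samples", "grid_height", "grid_width", "feature_dim",
                     "n_signatures", "signature_length"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        lo, hi = self.region_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError(
                f"region_fraction_range must satisfy 0 <= lo <= hi <= 1, "
                f"got ({lo}, {hi})")
        if not 0.0 < self.hazard_base < 1.0:
            raise ConfigurationError(
                f"hazard_base must lie in (0,1), got {self.hazard_base}")
        top = self.hazard_base + self.hazard_slope
        if not 0.0 < top < 1.0:
            raise ConfigurationError(
                f"hazard_base + hazard_slope must lie in (0,1), got {top}")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ConfigurationError(
                f"censor_rate must lie in [0,1], got {self.censor_rate}")


@dataclass
class SyntheticSample:
    """One synthetic subject: graph, planted mask, signatures, survival."""

    sample_id: str
    graph: ImagingGraph
    region_mask: np.ndarray
    signature_values: list[np.ndarray]
    time: float
    event: int
    prevalence: float = field(default=0.0)

    def __post_init__(self):
        if len(self.region_mask) != self.graph.n_nodes:
            raise ConfigurationError("region mask length != node count")
        if self.event not in (0, 1):
            raise ConfigurationError(f"event must be 0 or 1, got {self.event}")
        if self.time < 0:
            raise ConfigurationError(f"time must be >= 0, got {self.time}")


def _planted_rectangle(rng: np.random.Generator, h: int, w: int,
                       frac_range: tuple[float, float]) -> np.ndarray:
    """Boolean h x w mask of a random axis-aligned rectangle."""
    frac = rng.uniform(*frac_range)
    area = max(1.0, frac * h * w)
    rh = int(np.clip(round(np.sqrt(area * h / w)), 1, h))
    rw = int(np.clip(round(area / rh), 1, w))
    r0 = rng.integers(0, h - rh + 1)
    c0 = rng.integers(0, w - rw + 1)
    mask = np.zeros((h, w), dtype=bool)
    mask[r0:r0 + rh, c0:c0 + rw] = True
    return mask


def generate_cohort(config: SyntheticCohortConfig) -> list[SyntheticSample]:
    """Generate the cohort; deterministic given ``config.seed``."""
    config.validate()
    h, w, c = config.grid_height, config.grid_width, config.feature_dim
    coords = np.stack(np.meshgrid(np.arange(h), np.arange(w), indexing="ij"),
                      axis=-1).reshape(-1, 2)
    adjacency = build_adjacency(coords, connectivity=8)
    # per-signature loadings are cohort-level constants drawn from the base seed
    master = np.random.default_rng(config.seed)
    loadings = master.standard_normal(config.n_signatures)
    samples = []
    for i in range(config.n_samples):
        rng = np.random.default_rng(config.seed + i + 1)
        mask2d = _planted_rectangle(rng, h, w, config.region_fraction_range)
        mask = mask2d.reshape(-1)
        prevalence = float(mask.mean())
        feats = rng.standard_normal((h * w, c))
        feats[mask] += config.effect_size
        graph = ImagingGraph(feats.astype(np.float32), adjacency, coords,
                             patch_size=256, slide_id=f"synthetic_{i:04d}")
        sig_values = [
            prevalence * loadings[m]
            + rng.standard_normal(config.signature_length)
            for m in range(config.n_signatures)
        ]
        hazard = config.hazard_base + config.hazard_slope * prevalence
        d = 0
        while rng.random() >= hazard and d < _MAX_GEOMETRIC_BINS:
            d += 1
        time = (d + rng.random()) * config.bin_width_days
        event = 1
        if rng.random() < config.censor_rate:
            event = 0
            time = rng.uniform(0.0, time)
        samples.append(SyntheticSample(
            sample_id=f"synthetic_{i:04d}", graph=graph, region_mask=mask,
            signature_values=sig_values, time=float(time), event=event,
            prevalence=prevalence))
    return samples


def write_cohort(samples: list[SyntheticSample], directory,
                 seed: int | None = None, config: SyntheticCohortConfig | None = None):
    """Serialize a cohort: per-slide HDF5 graphs, CSV tables, manifest.

    Returns the manifest path. ``expression.csv`` holds one row per sample
    and one column per signature element (``sig{m}_g{p}``); ``survival.csv``
    has columns sample_id, time_days, event; ``region_masks.csv`` stores the
    planted ground-truth masks as 0/1 node vectors.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    expr_rows, surv_rows, mask_rows = [], [], []
    for s in samples:
        graph_file = f"{s.sample_id}.h5"
        save_graph(s.graph, directory / graph_file)
        entries.append({"sample_id": s.sample_id, "graph": graph_file,
                        "n_nodes": s.graph.n_nodes,
                        "prevalence": s.prevalence})
        row = {"sample_id": s.sample_id}
        for m, vec in enumerate(s.signature_values):
            for p, v in enumerate(vec):
                row[f"sig{m}_g{p}"] = v
        expr_rows.append(row)
        surv_rows.append({"sample_id": s.sample_id, "time_days": s.time,
                          "event": s.event})
        mask_rows.append({"sample_id": s.sample_id,
                          **{f"node{j}": int(v) for j, v in enumerate(s.region_mask)}})
    pd.DataFrame(expr_rows).to_csv(directory / "expression.csv", index=False)
    pd.DataFrame(surv_rows).to_csv(directory / "survival.csv", index=False)
    pd.DataFrame(mask_rows).to_csv(directory / "region_masks.csv", index=False)
    manifest = {
        "seed": seed,
        "n_samples": len(samples),
        "config": asdict(config) if config is not None else None,
        "files": entries,
        "tables": ["expression.csv", "survival.csv", "region_masks.csv"],
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_cohort(directory) -> list[SyntheticSample]:
    """Inverse of :func:`write_cohort`."""
    from .graphs import load_graph

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    expr = pd.read_csv(directory / "expression.csv",
                       float_precision="round_trip").set_index("sample_id")
    surv = pd.read_csv(directory / "survival.csv",
                       float_precision="round_trip").set_index("sample_id")
    masks = pd.read_csv(directory / "region_masks.csv").set_index("sample_id")
    sig_ids = sorted({c.split("_")[0] for c in expr.columns})
    samples = []
    for entry in manifest["files"]:
        sid = entry["sample_id"]
        graph = load_graph(directory / entry["graph"])
        sig_values = []
        for m in range(len(sig_ids)):
            cols = [c for c in expr.columns if c.startswith(f"sig{m}_")]
            sig_values.append(expr.loc[sid, cols].to_numpy(dtype=float))
        samples.append(SyntheticSample(
            sample_id=sid, graph=graph,
            region_mask=masks.loc[sid].to_numpy(dtype=bool),
            signature_values=sig_values,
            time=float(surv.loc[sid, "time_days"]),
            event=int(surv.loc[sid, "event"]),
            prevalence=float(entry.get("prevalence", 0.0))))
    return samples
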