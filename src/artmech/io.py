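"""On-disk cohort format.

A cohort directory contains::

    curves.csv       sample_id, direction (circ|axial), lambda, stress_kpa
    histology.csv    sample_id, phi_co, phi_ef, phi_smc
    structural.csv   sample_id, alpha_deg, kappa_ip, kappa_op
    plots/<id>.csv   68x54 intensity matrix (row 1 = outermost depth layer)
    plots/<id>.png   the same plot as 8-bit grayscale (for viewing)
    truth.csv        optional ground-truth table (synthetic cohorts)
    config.yaml      optional generation-config snapshot
    manifest.json    format version and file inventory

Angles are stored in degrees on disk and radians in memory.  Curves are
tidy long format, strictly increasing in stretch per (sample, direction).

Loading applies an automated monotonicity guard standing in for the
manual curation of raw test data: once the stress drops by more than a
configurable fraction (default 5%) of its running maximum -- a jump or
softening event -- the remainder of that curve is truncated with a logged
warning.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .constitutive import FibreArchitecture, MaterialParams, StressStretchCurve
from .errors import DomainError
from .fitting import HistologyFractions, SampleRecord
from .imaging import PLOT_COLS, PLOT_ROWS, IntensityPlot

__all__ = ["save_cohort", "load_cohort", "save_plot_png", "load_plot_png",
           "FORMAT_VERSION", "SOFTENING_THRESHOLD"]

log = logging.getLogger(__name__)

FORMAT_VERSION = 1

#: Fractional stress drop (of the running maximum) that triggers curve
#: truncation on load.
SOFTENING_THRESHOLD = 0.05

_FLOAT_FMT = "%.12g"


def save_plot_png(plot: IntensityPlot, path):
    """8-bit grayscale render of an intensity plot."""
    arr = np.clip(np.round(plot.grid * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def load_plot_png(path) -> IntensityPlot:
    arr = np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
    return IntensityPlot(arr)


def save_cohort(samples, root, truths=None, config=None):
    """Write a cohort directory (see module docstring for the layout)."""
    root = Path(root)
    (root / "plots").mkdir(parents=True, exist_ok=True)
    curve_rows, hist_rows, struct_rows = [], [], []
    for s in samples:
        for c in s.curves:
            for lam, sig in zip(c.stretch, c.stress):
                curve_rows.append((s.sample_id, c.direction, lam, sig))
        h = s.histology
        hist_rows.append((s.sample_id, h.phi_co, h.phi_ef, h.phi_smc))
        struct_rows.append((s.sample_id, s.arch.alpha_deg, s.arch.kappa_ip,
                            s.arch.kappa_op))
        if s.plot is not None:
            np.savetxt(root / "plots" / f"{s.sample_id}.csv", s.plot.grid,
                       delimiter=",", fmt=_FLOAT_FMT)
            save_plot_png(s.plot, root / "plots" / f"{s.sample_id}.png")
    pd.DataFrame(curve_rows, columns=["sample_id", "direction", "lambda",
                                      "stress_kpa"]).to_csv(
        root / "curves.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(hist_rows, columns=["sample_id", "phi_co", "phi_ef",
                                     "phi_smc"]).to_csv(
        root / "histology.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(struct_rows, columns=["sample_id", "alpha_deg", "kappa_ip",
                                       "kappa_op"]).to_csv(
        root / "structural.csv", index=False, float_format=_FLOAT_FMT)
    if truths is not None:
        pd.DataFrame([dataclasses.asdict(t) for t in truths]).to_csv(
            root / "truth.csv", index=False, float_format=_FLOAT_FMT)
    if config is not None:
        cfg = dataclasses.asdict(config) if dataclasses.is_dataclass(config) \
            else dict(config)
        with open(root / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "n_samples": len(samples),
        "sample_ids": [s.sample_id for s in samples],
        "has_truth": truths is not None,
    }
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def _truncate_softening(sid, direction, lam, sig,
                        threshold=SOFTENING_THRESHOLD):
    """Drop points after the first stress drop exceeding ``threshold`` of
    the running maximum (automated stand-in for manual curve cutoff)."""
    run_max = -np.inf
    for i, s in enumerate(sig):
        if s < run_max - threshold * abs(run_max):
            log.warning("sample %s (%s): softening at stretch %.4f; "
                        "truncating %d of %d points", sid, direction,
                        lam[i], len(sig) - i, len(sig))
            return lam[:i], sig[:i]
        run_max = max(run_max, s)
    return lam, sig


def load_cohort(root, softening_threshold=SOFTENING_THRESHOLD):
    """Load and validate a cohort directory into sample records.

    Returns (samples, truths) where truths is a DataFrame or None.
    Raises DomainError naming the offending sample and field.
    """
    root = Path(root)
    for fname in ("curves.csv", "histology.csv", "structural.csv"):
        if not (root / fname).exists():
            raise DomainError(f"missing cohort file {fname} in {root}")
    curves = pd.read_csv(root / "curves.csv")
    hist = pd.read_csv(root / "histology.csv").set_index("sample_id")
    struct = pd.read_csv(root / "structural.csv").set_index("sample_id")
    truth_df = None
    truth_params = {}
    if (root / "truth.csv").exists():
        truth_df = pd.read_csv(root / "truth.csv")
        for _, row in truth_df.iterrows():
            truth_params[row["sample_id"]] = MaterialParams(
                row["c"], row["k1"], row["k2"])

    samples = []
    for sid, group in curves.groupby("sample_id", sort=True):
        if sid not in hist.index:
            raise DomainError(f"sample {sid}: missing histology row")
        if sid not in struct.index:
            raise DomainError(f"sample {sid}: missing structural row")
        curve_objs = []
        for direction, sub in group.groupby("direction"):
            lam = sub["lambda"].to_numpy()
            sig = sub["stress_kpa"].to_numpy()
            order = np.argsort(lam)
            lam, sig = lam[order], sig[order]
            if np.any(np.diff(lam) <= 0):
                raise DomainError(
                    f"sample {sid} ({direction}): stretches not strictly "
                    "increasing")
            lam, sig = _truncate_softening(sid, direction, lam, sig,
                                           softening_threshold)
            if lam.size == 0:
                raise DomainError(
                    f"sample {sid} ({direction}): no points left after the "
                    "softening guard")
            curve_objs.append(StressStretchCurve(direction, lam, sig))
        h = hist.loc[sid]
        st = struct.loc[sid]
        plot = None
        pcsv = root / "plots" / f"{sid}.csv"
        ppng = root / "plots" / f"{sid}.png"
        if pcsv.exists():
            grid = np.loadtxt(pcsv, delimiter=",")
            if grid.shape != (PLOT_ROWS, PLOT_COLS):
                raise DomainError(f"sample {sid}: plot matrix has shape "
                                  f"{grid.shape}")
            plot = IntensityPlot(grid)
        elif ppng.exists():
            plot = load_plot_png(ppng)
        else:
            raise DomainError(f"sample {sid}: missing intensity plot")
        try:
            arch = FibreArchitecture.from_degrees(
                st["alpha_deg"], st["kappa_ip"], st["kappa_op"])
            fractions = HistologyFractions(h["phi_co"], h["phi_ef"],
                                           h["phi_smc"])
        except DomainError as err:
            raise DomainError(f"sample {sid}: {err}") from err
        samples.append(SampleRecord(
            sample_id=sid, curves=curve_objs, arch=arch, histology=fractions,
            plot=plot, ground_truth=truth_params.get(sid)))
    return samples, truth_df
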