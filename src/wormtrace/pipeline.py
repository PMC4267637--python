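"""End-to-end virtual experiments: simulate -> render -> trace -> measure.

Three orchestrated runs mirror the stages of the study:

* :func:`run_reference_mc` — simulate planar chains at base-pair
  resolution, resample them at AFM link lengths and build the reference
  bend-angle distributions and persistence-length estimates;
* :func:`run_noise_experiment` — add bisector-shift width noise to the
  resampled contours and track how the apparent persistence length degrades
  with noise amplitude and link length;
* :func:`run_imaging_experiment` — render chains into virtual AFM images,
  trace them (with and without refinement) and compare traced statistics to
  the generating truth.

Every run is driven by an :class:`ExperimentConfig` with a mandatory seed;
outputs carry the config hash and seed so reruns are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bendstats, io, polymer, tracing, virtual_afm
from ._geometry import point_at_arc
from .polymer import BP_STEP_NM, EnergyModel
from .virtual_afm import FixtureConfig, RenderParams

log = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Study conditions of one virtual experiment.

    Defaults are the reference conditions used throughout: 4363-bead
    chains (one bead per base pair, 0.34 nm), harmonic bending at
    ``lb = 56 nm``, link lengths 3.5 and 7 nm, pixel size 1.95 nm.
    ``n_molecules`` defaults to a desk-scale ensemble.
    """

    seed: int = 0
    model_kind: str = "harmonic"
    lb_nm: float = 56.0
    theta0_deg: float = 2.0
    k: int = 2
    q_kcal_mol: float = 110.0
    n_molecules: int = 100
    n_beads: int = 4363
    step_nm: float = BP_STEP_NM
    l0_nm: tuple = (3.5, 7.0)
    separations_links: tuple = (1,)
    noise_amplitudes_nm: tuple = (0.0, 1.0, 2.0)
    pixel_size_nm: float = 1.95
    render: RenderParams = field(default_factory=RenderParams)
    refine: bool = True
    termination_fraction: float = 0.25
    bin_width_rad: float = 0.05
    n_boot: int = 1000
    outdir: str | None = None

    def model(self) -> EnergyModel:
        if self.model_kind == "harmonic":
            return EnergyModel(kind="harmonic", lb=self.lb_nm)
        return EnergyModel(
            kind="lsec",
            theta0=np.deg2rad(self.theta0_deg),
            k=self.k,
            q=self.q_kcal_mol,
        )

    def validate(self) -> None:
        self.model()  # parameter validation happens in EnergyModel
        if self.n_molecules < 1 or self.n_beads < 2:
            raise ValueError("need at least one molecule of >= 2 beads")
        if not self.l0_nm:
            raise ValueError("l0_nm must be non-empty")
        if any(l0 < self.step_nm for l0 in self.l0_nm):
            raise ValueError("every l0 must be >= the bead step")
        if any(a < 0 for a in self.noise_amplitudes_nm):
            raise ValueError("noise amplitudes must be >= 0")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = io.load_config_yaml(path) or {}
        kwargs = {}
        model = raw.get("model", {})
        mapping = {
            "kind": "model_kind",
            "lb_nm": "lb_nm",
            "theta0_deg": "theta0_deg",
            "k": "k",
            "q_kcal_mol": "q_kcal_mol",
        }
        for src, dst in mapping.items():
            if src in model:
                kwargs[dst] = model[src]
        chain = raw.get("chain", {})
        if "n_beads" in chain:
            kwargs["n_beads"] = chain["n_beads"]
        if "n_molecules" in chain:
            kwargs["n_molecules"] = chain["n_molecules"]
        if "step_nm" in chain:
            kwargs["step_nm"] = chain["step_nm"]
        resample = raw.get("resample", {})
        if "l0_nm" in resample:
            l0 = resample["l0_nm"]
            kwargs["l0_nm"] = tuple(np.atleast_1d(l0).tolist())
        noise = raw.get("noise", {})
        if "amplitude_nm" in noise:
            kwargs["noise_amplitudes_nm"] = tuple(
                np.atleast_1d(noise["amplitude_nm"]).tolist()
            )
        render = raw.get("render", {})
        if render:
            kwargs["render"] = RenderParams(**render)
        for key in (
            "seed",
            "pixel_size_nm",
            "refine",
            "bin_width_rad",
            "n_boot",
            "outdir",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _simulate_chains(config: ExperimentConfig, rng) -> list:
    model = config.model()
    return [
        polymer.sample_chain(model, config.n_beads, config.step_nm, rng)
        for _ in range(config.n_molecules)
    ]


def _meta(config: ExperimentConfig) -> dict:
    return {"config_hash": config.digest(), "seed": config.seed}


def _maybe_write(config, tables, estimates_df, tag):
    if config.outdir is None:
        return
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key, table in tables.items():
        name = "_".join(str(k).replace(".", "p") for k in key)
        io.write_distribution_tsv(outdir / f"{tag}_dist_{name}.tsv", table,
                                  lb_reference=config.lb_nm)
    payload = _meta(config)
    payload["estimates"] = estimates_df.to_dict(orient="records")
    (outdir / f"{tag}_estimates.json").write_text(json.dumps(payload, indent=1))


def run_reference_mc(config: ExperimentConfig, rng: np.random.Generator | None = None):
    """Reference WLC distributions from stride-resampled simulated chains.

    Returns a dict with ``estimates`` (DataFrame: one row per link length x
    tangent separation), ``tables`` (keyed by ``(l0, L)``) and ``meta``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t0 = time.perf_counter()
    chains = _simulate_chains(config, rng)
    tables, rows = {}, []
    for l0 in config.l0_nm:
        contours = [polymer.resample_with_stride(c, l0) for c in chains]
        for sep in config.separations_links:
            sample = bendstats.collect_angles(contours, sep)
            est = bendstats.estimate_lb(sample, "variance", n_boot=config.n_boot, rng=rng)
            table = bendstats.neg_log_distribution(sample, config.bin_width_rad)
            tables[(l0, round(sample.separation, 3))] = table
            rows.append(
                {
                    "l0_nm": l0,
                    "L_nm": sample.separation,
                    "method": est.method,
                    "lb_nm": est.lb,
                    "stderr_nm": est.stderr,
                    "n_angles": est.n_angles,
                }
            )
    df = pd.DataFrame(rows)
    log.info("reference MC: %d chains in %.1f s", len(chains), time.perf_counter() - t0)
    _maybe_write(config, tables, df, "reference")
    return {"estimates": df, "tables": tables, "meta": _meta(config)}


def run_noise_experiment(config: ExperimentConfig, rng: np.random.Generator | None = None):
    """Apparent persistence length vs bisector-noise amplitude.

    For every amplitude and link length, resampled contours are perturbed
    along interior-angle bisectors and re-measured; amplitude 0 reproduces
    the clean reference.
    """
    config.validate()
    if not config.noise_amplitudes_nm:
        raise ValueError("noise_amplitudes_nm must be non-empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chains = _simulate_chains(config, rng)
    tables, rows = {}, []
    for l0 in config.l0_nm:
        clean = [polymer.resample_with_stride(c, l0) for c in chains]
        for amp in config.noise_amplitudes_nm:
            contours = (
                clean
                if amp == 0
                else [polymer.apply_bisector_noise(c, amp, rng) for c in clean]
            )
            for sep in config.separations_links:
                sample = bendstats.collect_angles(contours, sep)
                est = bendstats.estimate_lb(sample, "variance", n_boot=config.n_boot, rng=rng)
                tables[(l0, amp, round(sample.separation, 3))] = bendstats.neg_log_distribution(
                    sample, config.bin_width_rad
                )
                rows.append(
                    {
                        "l0_nm": l0,
                        "amplitude_nm": amp,
                        "L_nm": sample.separation,
                        "lb_nm": est.lb,
                        "stderr_nm": est.stderr,
                        "n_angles": est.n_angles,
                    }
                )
    df = pd.DataFrame(rows)
    _maybe_write(config, tables, df, "noise")
    return {"estimates": df, "tables": tables, "meta": _meta(config)}


def _seed_pair(centerline: np.ndarray, l0: float) -> np.ndarray:
    """Automatic seeding from ground truth: chain start plus a point one
    link length along the centerline (stands in for the interactive seeds
    used on real scans)."""
    return np.vstack([centerline[0], point_at_arc(centerline, l0)])


def run_imaging_experiment(config: ExperimentConfig, rng: np.random.Generator | None = None):
    """Render, trace and score the full virtual AFM experiment.

    For each molecule a virtual scan is rendered; it is traced at every
    requested link length with refinement off and on, the traced contours
    are measured exactly like the reference MC, and the ground-truth chains
    are resampled at the same link lengths for comparison.  Per-molecule
    tracing failures are logged and skipped.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fixture_cfg = FixtureConfig(
        n_molecules=config.n_molecules,
        n_beads=config.n_beads,
        step=config.step_nm,
        lb=config.lb_nm,
        pixel_size=config.pixel_size_nm,
        render=config.render,
    )
    fixtures = virtual_afm.make_fixture_set(fixture_cfg, rng)
    rows = []
    failures = 0
    traced_store: dict = {}
    for l0 in config.l0_nm:
        for refined in (False, True) if config.refine else (False,):
            contours = []
            for fx in fixtures:
                try:
                    trace = tracing.trace_molecule(
                        fx.image,
                        _seed_pair(fx.centerline, l0),
                        l0,
                        termination_fraction=config.termination_fraction,
                        image_ref=str(fx.index),
                    )
                    if refined:
                        trace = tracing.refine_trace(fx.image, trace)
                    contours.append(trace.as_contour())
                except (ValueError, RuntimeError) as exc:  # lost ridge etc.
                    failures += 1
                    log.warning("molecule %d at l0=%.2f failed: %s", fx.index, l0, exc)
            if len(contours) < 2:
                continue
            traced_store[(l0, refined)] = contours
            for sep in config.separations_links:
                sample = bendstats.collect_angles(contours, sep)
                est = bendstats.estimate_lb(sample, "variance", n_boot=config.n_boot, rng=rng)
                rows.append(
                    {
                        "l0_nm": l0,
                        "refined": refined,
                        "kind": "traced",
                        "L_nm": sample.separation,
                        "lb_nm": est.lb,
                        "stderr_nm": est.stderr,
                        "n_angles": est.n_angles,
                        "n_molecules": len(contours),
                    }
                )
        truth = [polymer.resample_with_stride(fx.chain, l0) for fx in fixtures]
        for sep in config.separations_links:
            sample = bendstats.collect_angles(truth, sep)
            est = bendstats.estimate_lb(sample, "variance", n_boot=config.n_boot, rng=rng)
            rows.append(
                {
                    "l0_nm": l0,
                    "refined": None,
                    "kind": "truth",
                    "L_nm": sample.separation,
                    "lb_nm": est.lb,
                    "stderr_nm": est.stderr,
                    "n_angles": est.n_angles,
                    "n_molecules": len(truth),
                }
            )
    df = pd.DataFrame(rows)
    result = {
        "estimates": df,
        "fixtures": fixtures,
        "traced": traced_store,
        "failures": failures,
        "meta": _meta(config),
    }
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        payload = _meta(config)
        payload["failures"] = failures
        payload["estimates"] = df.to_dict(orient="records")
        (outdir / "imaging_report.json").write_text(json.dumps(payload, indent=1))
    return result
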