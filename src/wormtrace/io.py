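"""File formats used between pipeline stages.

* chains / contours / traces — CSV with columns ``molecule_id,
  vertex_index, x_nm, y_nm``, one file per ensemble;
* height images — 32-bit float TIFF (heights in nm) plus a JSON sidecar
  carrying ``pixel_size_nm`` and provenance (seed, render parameters); the
  same pair is accepted for real flattened scans;
* distribution tables — TSV with ``theta_rad, theta_sq, count, neg_log_p``
  and optionally ``analytic_neg_log_p``;
* persistence estimates — JSON;
* experiment configuration — YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .bendstats import DistributionTable, PersistenceEstimate, analytic_wlc_neglogp
from .virtual_afm import HeightImage


def write_contours_csv(path, contours) -> None:
    """Write an ensemble of polylines.

    ``contours`` is an iterable of ``(molecule_id, (n, 2) array)`` pairs, or
    of objects with a ``vertices``/``positions`` attribute (then enumerated).
    """
    rows = []
    for item in contours:
        if isinstance(item, tuple):
            mol_id, pts = item
        else:
            mol_id = getattr(item, "index", None)
            pts = getattr(item, "vertices", None)
            if pts is None:
                pts = item.positions
        pts = np.asarray(pts, dtype=float)
        if mol_id is None:
            mol_id = len({r[0] for r in rows})
        for i, (x, y) in enumerate(pts):
            rows.append((mol_id, i, x, y))
    df = pd.DataFrame(rows, columns=["molecule_id", "vertex_index", "x_nm", "y_nm"])
    df.to_csv(path, index=False)


def read_contours_csv(path) -> list[tuple[object, np.ndarray]]:
    """Read back ``write_contours_csv`` output as (id, array) pairs."""
    df = pd.read_csv(path)
    out = []
    for mol_id, grp in df.groupby("molecule_id", sort=True):
        grp = grp.sort_values("vertex_index")
        out.append((mol_id, grp[["x_nm", "y_nm"]].to_numpy(dtype=float)))
    return out


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_height_image(path, image: HeightImage, seed=None, render_params=None) -> None:
    path = Path(path)
    tifffile.imwrite(path, image.heights.astype(np.float32))
    meta = {"pixel_size_nm": image.pixel_size}
    if seed is not None:
        meta["seed"] = int(seed)
    if render_params is not None:
        if dataclasses.is_dataclass(render_params):
            render_params = dataclasses.asdict(render_params)
        meta["render_params"] = render_params
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_height_image(path) -> HeightImage:
    path = Path(path)
    heights = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    return HeightImage(heights=heights, pixel_size=float(meta["pixel_size_nm"]))


def write_distribution_tsv(path, table: DistributionTable, lb_reference: float | None = None) -> None:
    """Write a binned distribution; optionally add the analytic WLC column."""
    df = pd.DataFrame(
        {
            "theta_rad": table.bin_centers,
            "theta_sq": table.linearized_x,
            "count": table.counts,
            "neg_log_p": table.neg_log_p,
        }
    )
    if lb_reference is not None:
        ref = analytic_wlc_neglogp(table.bin_centers, table.separation, lb_reference)
        if table.folded:
            ref = ref - np.log(2.0)  # folded |theta| doubles the density
        df["analytic_neg_log_p"] = ref
    df.to_csv(path, sep="\t", index=False)


def estimate_to_dict(est: PersistenceEstimate) -> dict:
    return {
        "lb_nm": est.lb,
        "stderr_nm": est.stderr,
        "method": est.method,
        "L_nm": est.separation,
        "n_angles": est.n_angles,
    }


def write_estimates_json(path, estimates, extra: dict | None = None) -> None:
    payload = {"estimates": [estimate_to_dict(e) for e in estimates]}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1))


def load_config_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_config_yaml(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
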