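"""End-to-end orchestration: generate/load data, extract features, classify.

The pipeline chains the stages: synthetic population (or a manifest of real
height maps and landmark files) -> median denoising -> supraorbital-margin
features (area, erosion thickness) -> frontal Fourier amplitudes
(P'_1..P'_16) -> fused 18-dimensional feature vectors -> stratified 70/30
split -> z-scoring by training stats -> (C, delta) grid search ->
confusion-count evaluation.  Every run is reproducible from (config, seed);
outputs (features CSV, model JSON, report JSON) carry a config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from craniosex import synthetic
from craniosex.frontal import extract_frontal_features
from craniosex.margin import MarginConfig, SurfaceHeightMap, extract_margin_features
from craniosex.preprocess import median_filter
from craniosex.svm import (
    EvalReport,
    Standardizer,
    evaluate,
    grid_search,
    solve_dual,
    stratified_split,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "PipelineResult",
    "run_pipeline",
    "extract_features",
    "read_heightmap_csv",
    "write_heightmap_csv",
    "read_landmarks_csv",
    "read_obj_heightmap",
    "save_model_json",
    "load_model_json",
]

FEATURE_NAMES = ["area", "thickness"] + [f"P{k}" for k in range(1, 17)]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of a full run (see docs/methods.md for rationale)."""

    n_male: int = 73
    n_female: int = 60
    margin: MarginConfig = field(default_factory=MarginConfig)
    median_window: int = 3
    degree: int = 6
    folds: int = 5
    train_frac: float = 0.7
    seed: int = 0
    grid_max_iter: int = 3000
    out_dir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(
            {**{k: v for k, v in asdict(self).items() if k != "out_dir"}},
            sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class PipelineResult:
    features: pd.DataFrame
    report: EvalReport
    model: object
    search: object
    train_idx: np.ndarray
    test_idx: np.ndarray
    config_hash: str


def _denoise_margin(surface: SurfaceHeightMap, window: int) -> SurfaceHeightMap:
    """Median-filter the height map (applied on heights, any range)."""
    h = surface.heights
    lo, hi = float(h.min()), float(h.max())
    if hi - lo < 1e-12:
        return surface
    norm = (h - lo) / (hi - lo)
    filtered = median_filter(norm, window=window) * (hi - lo) + lo
    return SurfaceHeightMap(heights=filtered, spacing=surface.spacing)


def extract_features(individuals, margin_config: MarginConfig = MarginConfig(),
                     median_window: int = 3, degree: int = 6) -> pd.DataFrame:
    """Fused per-individual feature table: id, sex, area, thickness, P'_1..16."""
    rows = []
    for ind in individuals:
        surface = _denoise_margin(ind.margin, median_window)
        try:
            vf = extract_margin_features(surface, margin_config)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"margin stage failed for {ind.id}: {exc}") from exc
        try:
            pnorm = extract_frontal_features(ind.frontal_landmarks, degree=degree)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"frontal stage failed for {ind.id}: {exc}") from exc
        rows.append({"id": ind.id, "sex": ind.sex_label,
                     "area": vf.area, "thickness": vf.thickness,
                     **{f"P{k + 1}": pnorm[k] for k in range(16)}})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig = PipelineConfig(),
                 individuals=None) -> PipelineResult:
    """Execute the full chain; see module docstring.

    ``individuals`` may be a pre-built list of
    :class:`~craniosex.synthetic.SyntheticIndividual`-like records; by
    default a synthetic population of (n_male, n_female) is generated from
    the config seed.
    """
    if individuals is None:
        try:
            individuals = synthetic.generate_population(
                config.n_male, config.n_female, seed=config.seed)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"synthesis stage failed: {exc}") from exc
    if not individuals:
        raise PipelineError("synthesis stage produced no individuals")

    features = extract_features(individuals, config.margin,
                                config.median_window, config.degree)
    X = features[FEATURE_NAMES].to_numpy(dtype=float)
    y = features["sex"].to_numpy(dtype=float)

    try:
        train_idx, test_idx = stratified_split(y, config.train_frac, config.seed)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"split stage failed: {exc}") from exc

    scaler = Standardizer.fit(X[train_idx])
    Xtr = scaler.transform(X[train_idx])
    ytr, yte = y[train_idx], y[test_idx]

    try:
        search = grid_search(Xtr, ytr, folds=config.folds, seed=config.seed,
                             max_iter=config.grid_max_iter)
        model = solve_dual(Xtr, ytr, C=search.best_C, delta=search.best_delta,
                           max_iter=50 * config.grid_max_iter, strict=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"training stage failed: {exc}") from exc
    object.__setattr__(model, "standardizer", scaler)

    try:
        # the model's standardizer maps raw features to the training scale
        report = evaluate(model, X[test_idx], yte)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"evaluation stage failed: {exc}") from exc

    result = PipelineResult(features=features, report=report, model=model,
                            search=search, train_idx=train_idx,
                            test_idx=test_idx,
                            config_hash=config.config_hash())
    if config.out_dir is not None:
        _write_artifacts(result, config)
    return result


def _write_artifacts(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(out / "features.csv", index=False)
    save_model_json(result.model, out / "model.json")
    payload = {
        "config_hash": result.config_hash,
        "seed": config.seed,
        "n_train": int(len(result.train_idx)),
        "n_test": int(len(result.test_idx)),
        "best_C": result.search.best_C,
        "best_delta": result.search.best_delta,
        "cv_accuracy": result.search.best_accuracy,
        "report": result.report.as_dict(),
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# File I/O


def write_heightmap_csv(surface: SurfaceHeightMap, path) -> None:
    np.savetxt(path, surface.heights, delimiter=",")


def read_heightmap_csv(path, spacing: float | None = None) -> SurfaceHeightMap:
    heights = np.loadtxt(path, delimiter=",")
    kwargs = {} if spacing is None else {"spacing": spacing}
    return SurfaceHeightMap(heights=heights, **kwargs)


def read_landmarks_csv(path) -> np.ndarray:
    pts = np.loadtxt(path, delimiter=",")
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"{path}: expected rows of x,y,z")
    return pts


def save_model_json(model, path) -> None:
    payload = {
        "support_vectors": model.support_vectors.tolist(),
        "support_alphas": model.support_alphas.tolist(),
        "support_labels": model.support_labels.tolist(),
        "bias": model.bias,
        "C": model.C,
        "delta": model.delta,
        "standardizer": None if model.standardizer is None else {
            "mean": model.standardizer.mean.tolist(),
            "sd": model.standardizer.sd.tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_model_json(path):
    from craniosex.svm import SVMModel

    d = json.loads(Path(path).read_text())
    scaler = None
    if d["standardizer"] is not None:
        scaler = Standardizer(mean=np.asarray(d["standardizer"]["mean"]),
                              sd=np.asarray(d["standardizer"]["sd"]))
    return SVMModel(
        support_vectors=np.asarray(d["support_vectors"], dtype=float),
        support_alphas=np.asarray(d["support_alphas"], dtype=float),
        support_labels=np.asarray(d["support_labels"], dtype=float),
        bias=float(d["bias"]), C=float(d["C"]), delta=float(d["delta"]),
        dual_objective=float("nan"), kkt_gap=float("nan"),
        n_iter=0, converged=True, standardizer=scaler,
    )


def read_obj_heightmap(mesh_path, grid_shape: tuple[int, int] = (64, 64),
                       view: str = "front") -> SurfaceHeightMap:
    """Orthographic depth render of an OBJ mesh onto a regular grid.

    Frontal view convention: x right, y up, z toward the viewer; each grid
    cell takes the nearest-surface (largest z) depth of any triangle
    covering its center.  Cells no triangle covers are inpainted by nearest
    neighbor.  Degenerate or empty meshes are rejected.
    """
    import trimesh

    mesh = trimesh.load(str(mesh_path), force="mesh", process=False)
    if mesh.is_empty or len(mesh.faces) == 0:
        raise ValueError(f"{mesh_path}: empty or faceless mesh")
    if view != "front":
        raise ValueError("only the frontal orthographic view is supported")
    rows, cols = grid_shape
    v = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=int)
    xmin, ymin = v[:, 0].min(), v[:, 1].min()
    xmax, ymax = v[:, 0].max(), v[:, 1].max()
    if xmax - xmin < 1e-12 or ymax - ymin < 1e-12:
        raise ValueError(f"{mesh_path}: degenerate mesh footprint")
    xs = np.linspace(xmin, xmax, cols)
    ys = np.linspace(ymin, ymax, rows)
    height = np.full((rows, cols), -np.inf)
    for tri in faces:
        p = v[tri]
        txmin, txmax = p[:, 0].min(), p[:, 0].max()
        tymin, tymax = p[:, 1].min(), p[:, 1].max()
        ci = np.flatnonzero((xs >= txmin - 1e-12) & (xs <= txmax + 1e-12))
        ri = np.flatnonzero((ys >= tymin - 1e-12) & (ys <= tymax + 1e-12))
        if ci.size == 0 or ri.size == 0:
            continue
        gx, gy = np.meshgrid(xs[ci], ys[ri])
        # barycentric coordinates in the xy-projection
        a, b, c = p[0, :2], p[1, :2], p[2, :2]
        det = (b[1] - c[1]) * (a[0] - c[0]) + (c[0] - b[0]) * (a[1] - c[1])
        if abs(det) < 1e-15:
            continue
        l1 = ((b[1] - c[1]) * (gx - c[0]) + (c[0] - b[0]) * (gy - c[1])) / det
        l2 = ((c[1] - a[1]) * (gx - c[0]) + (a[0] - c[0]) * (gy - c[1])) / det
        l3 = 1.0 - l1 - l2
        inside = (l1 >= -1e-9) & (l2 >= -1e-9) & (l3 >= -1e-9)
        z = l1 * p[0, 2] + l2 * p[1, 2] + l3 * p[2, 2]
        block = height[np.ix_(ri, ci)]
        block[inside] = np.maximum(block[inside], z[inside])
        height[np.ix_(ri, ci)] = block
    missing = ~np.isfinite(height)
    if missing.all():
        raise ValueError(f"{mesh_path}: mesh does not cover the grid")
    if missing.any():
        from scipy import ndimage

        idx = ndimage.distance_transform_edt(missing, return_distances=False,
                                             return_indices=True)
        height = height[tuple(idx)]
    return SurfaceHeightMap(heights=height)
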