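"""Unified command-line interface, run configuration, and the end-to-end demo.

All randomness funnels through explicit seeds in :class:`RunConfig`; every
subcommand is deterministic given its config. Logs go to stderr, artifacts to
the ``--out`` directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import yaml

from . import __version__

logger = logging.getLogger("tmsfield")


# --------------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------------- #


@dataclass
class HeadConfig:
    grid_n: int = 48
    voxel_mm: float = 2.5
    outer_radius_mm: float = 56.0
    anisotropy_ratio: float = 1.0   # 1 = isotropic white matter
    seed: int = 0


@dataclass
class CoilConfig:
    loop_radius_mm: float = 27.0
    loop_center_offset_mm: float = 27.0
    segments_per_loop: int = 64
    dIdt: float = 1.0e6
    standoff_mm: float = 2.0


@dataclass
class PlacementConfig:
    n_cases: int = 300
    n_directions: int = 78
    seed: int = 0


@dataclass
class SolverConfig:
    tol: float = 1.0e-8
    max_iter: int | None = None


@dataclass
class TrainConfig:
    levels: int = 3
    base_channels: int = 8
    epochs: int = 100
    batch_size: int = 4
    learning_rate: float = 2.0e-3
    warmup_frac: float = 0.05
    seed: int = 0


@dataclass
class ServerConfig:
    host: str = "127.0.0.1"
    port: int = 18944          # the OpenIGTLink registered port
    n_runs: int = 50


@dataclass
class RunConfig:
    head: HeadConfig = field(default_factory=HeadConfig)
    coil: CoilConfig = field(default_factory=CoilConfig)
    placements: PlacementConfig = field(default_factory=PlacementConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    server: ServerConfig = field(default_factory=ServerConfig)
    fov_shape: tuple[int, int, int] = (24, 24, 24)
    seed: int = 0


def _build_dataclass(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} under '{path}'")
    kwargs = {}
    for key, val in data.items():
        f = fields[key]
        if dataclasses.is_dataclass(f.type) or f.type in (
                HeadConfig, CoilConfig, PlacementConfig, SolverConfig,
                TrainConfig, ServerConfig):
            if not isinstance(val, dict):
                raise ValueError(f"config section '{path}.{key}' must be a mapping")
            kwargs[key] = _build_dataclass(f.type, val, f"{path}.{key}")
        elif key == "fov_shape":
            kwargs[key] = tuple(int(v) for v in val)
        else:
            kwargs[key] = val
    return cls(**kwargs)


_SECTION_TYPES = {
    "head": HeadConfig, "coil": CoilConfig, "placements": PlacementConfig,
    "solver": SolverConfig, "train": TrainConfig, "server": ServerConfig,
}


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(data) - (set(_SECTION_TYPES) | {"fov_shape", "seed"})
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} at the root")
    cfg = RunConfig()
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            setattr(cfg, name, _build_dataclass(cls, data[name], name))
    if "fov_shape" in data:
        cfg.fov_shape = tuple(int(v) for v in data["fov_shape"])
    if "seed" in data:
        cfg.seed = int(data["seed"])
    return cfg


def _apply_seed(cfg: RunConfig, seed: int | None) -> RunConfig:
    """A --seed flag overrides every per-section seed (offset for independence)."""
    if seed is None:
        return cfg
    cfg.seed = int(seed)
    cfg.head.seed = int(seed)
    cfg.placements.seed = int(seed) + 1
    cfg.train.seed = int(seed) + 2
    return cfg


def _make_head(cfg: RunConfig):
    from . import headmodel

    cv, geom = headmodel.make_sphere_head(
        outer_radius_mm=cfg.head.outer_radius_mm,
        grid_shape=(cfg.head.grid_n,) * 3,
        voxel_mm=cfg.head.voxel_mm,
        seed=cfg.head.seed,
    )
    if cfg.head.anisotropy_ratio > 1.0:
        wm = (0.35 * geom.white_matter_radius, geom.white_matter_radius)
        cv = headmodel.randomize_conductivity_tensors(
            cv, wm, cfg.head.anisotropy_ratio, seed=cfg.head.seed)
    return cv, geom


def _make_coil(cfg: RunConfig):
    from . import coilmodel

    return coilmodel.make_figure8_coil(
        loop_radius_mm=cfg.coil.loop_radius_mm,
        loop_center_offset_mm=cfg.coil.loop_center_offset_mm,
        segments_per_loop=cfg.coil.segments_per_loop,
        dIdt=cfg.coil.dIdt,
    )


# --------------------------------------------------------------------------- #
# CLI
# --------------------------------------------------------------------------- #


def _common(func):
    func = click.option("--config", "config_path", type=click.Path(exists=True),
                        default=None, help="YAML run configuration")(func)
    func = click.option("--seed", type=int, default=None,
                        help="override all config seeds")(func)
    func = click.option("--out", "out_dir", type=click.Path(), default="out",
                        help="artifact output directory")(func)
    return func


def _setup(config_path, seed, out_dir) -> tuple[RunConfig, Path]:
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
    cfg = _apply_seed(load_config(config_path), seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return cfg, out


@click.group()
@click.version_option(version=__version__, prog_name="tmsfield")
def main() -> None:
    """TMS E-field modelling toolkit."""


@main.command("make-head")
@_common
def cli_make_head(config_path, seed, out_dir) -> None:
    """Generate a synthetic spherical head (conductivity, mask, meshes, fibers)."""
    from . import geometry, headmodel

    cfg, out = _setup(config_path, seed, out_dir)
    cv, geom = _make_head(cfg)
    geometry.save_volume_nifti(cv.tensors, out / "conductivity.nii.gz")
    geometry.save_volume_nifti(cv.mask, out / "mask.nii.gz")
    geometry.save_mesh(geom.scalp_mesh, out / "scalp.stl")
    geometry.save_mesh(geom.gm_mesh, out / "gray_matter.stl")
    fibers = headmodel.make_synthetic_streamlines(geom, n=50, seed=cfg.head.seed)
    geometry.save_streamlines(fibers, out / "fibers.trk")
    logger.info("head written to %s (%d mask voxels)", out, int(cv.mask.values.sum()))


@main.command("sample-placements")
@_common
def cli_sample_placements(config_path, seed, out_dir) -> None:
    """Sample coil placements at 10-10 sites and write them as CSV."""
    from . import coilmodel

    cfg, out = _setup(config_path, seed, out_dir)
    _, geom = _make_head(cfg)
    ps = coilmodel.sample_placements(
        geom, n_cases=cfg.placements.n_cases,
        n_directions=cfg.placements.n_directions,
        seed=cfg.placements.seed, standoff_mm=cfg.coil.standoff_mm)
    ps.to_dataframe().to_csv(out / "placements.csv", index=False)
    logger.info("%d placements written to %s", len(ps), out / "placements.csv")


@main.command("dadt")
@_common
@click.option("--pose", "pose_path", type=click.Path(exists=True), default=None,
              help="4x4 coil pose matrix (text); default: vertex placement")
def cli_dadt(config_path, seed, out_dir, pose_path) -> None:
    """Evaluate the coil's dA/dt field on the head grid and write NIfTI."""
    from . import coilmodel, geometry

    cfg, out = _setup(config_path, seed, out_dir)
    cv, geom = _make_head(cfg)
    coil = _make_coil(cfg)
    if pose_path:
        pose = coilmodel.CoilPose(geometry.load_transform(pose_path))
    else:
        pose = coilmodel.pose_at_site(geom, np.array([0.0, 0.0, 1.0]), 0.0,
                                      standoff_mm=cfg.coil.standoff_mm)
    fld = coilmodel.dadt_field(coil, pose, cv.tensors)
    geometry.save_volume_nifti(fld, out / "dadt.nii.gz")
    logger.info("dA/dt written to %s", out / "dadt.nii.gz")


@main.command("solve")
@_common
@click.option("--pose", "pose_path", type=click.Path(exists=True), default=None)
def cli_solve(config_path, seed, out_dir, pose_path) -> None:
    """Ground-truth quasi-static solve: writes phi and E as NIfTI."""
    from . import coilmodel, fieldsolver, geometry

    cfg, out = _setup(config_path, seed, out_dir)
    cv, geom = _make_head(cfg)
    coil = _make_coil(cfg)
    if pose_path:
        pose = coilmodel.CoilPose(geometry.load_transform(pose_path))
    else:
        pose = coilmodel.pose_at_site(geom, np.array([0.0, 0.0, 1.0]), 0.0,
                                      standoff_mm=cfg.coil.standoff_mm)
    dadt = coilmodel.dadt_field(coil, pose, cv.tensors)
    pot = fieldsolver.solve_potential_fdm(cv, dadt, tol=cfg.solver.tol,
                                          max_iter=cfg.solver.max_iter)
    e = fieldsolver.total_efield(dadt, pot)
    geometry.save_volume_nifti(pot.phi, out / "phi.nii.gz")
    geometry.save_volume_nifti(e, out / "efield.nii.gz")
    logger.info("solve done: residual %.2e in %d iterations", pot.residual, pot.n_iter)


@main.command("make-dataset")
@_common
def cli_make_dataset(config_path, seed, out_dir) -> None:
    """Generate ground-truth training cases into an HDF5 container."""
    from . import coilmodel, fieldsolver

    cfg, out = _setup(config_path, seed, out_dir)
    cv, geom = _make_head(cfg)
    coil = _make_coil(cfg)
    ps = coilmodel.sample_placements(
        geom, n_cases=cfg.placements.n_cases,
        n_directions=cfg.placements.n_directions,
        seed=cfg.placements.seed, standoff_mm=cfg.coil.standoff_mm)
    samples = fieldsolver.make_dataset(geom, cv, coil, ps,
                                       fov_shape=cfg.fov_shape, tol=cfg.solver.tol)
    fieldsolver.save_dataset(samples, out / "dataset.h5")
    logger.info("%d cases written to %s", len(samples), out / "dataset.h5")


@main.command("train")
@_common
@click.option("--dataset", "dataset_path", type=click.Path(exists=True), required=True)
def cli_train(config_path, seed, out_dir, dataset_path) -> None:
    """Train the surrogate on an HDF5 dataset; writes checkpoint + history CSV."""
    import pandas as pd

    from . import fieldsolver, surrogate

    cfg, out = _setup(config_path, seed, out_dir)
    samples = fieldsolver.load_dataset(dataset_path)
    scfg = surrogate.SurrogateConfig(
        levels=cfg.train.levels, base_channels=cfg.train.base_channels,
        epochs=cfg.train.epochs, batch_size=cfg.train.batch_size,
        learning_rate=cfg.train.learning_rate, warmup_frac=cfg.train.warmup_frac,
        seed=cfg.train.seed)
    model = surrogate.train_surrogate(samples, scfg)
    surrogate.save_model(model, out / "surrogate.npz")
    pd.DataFrame(model.history).to_csv(out / "history.csv", index=False)
    logger.info("trained %d epochs; final train NE %.3f",
                scfg.epochs, model.history[-1]["train_ne"])


@main.command("predict")
@_common
@click.option("--model", "model_path", type=click.Path(exists=True), required=True)
@click.option("--pose", "pose_path", type=click.Path(exists=True), default=None)
def cli_predict(config_path, seed, out_dir, model_path, pose_path) -> None:
    """Predict the E-field for a coil pose; writes vector + magnitude NIfTI."""
    from . import coilmodel, geometry, streaming, surrogate

    cfg, out = _setup(config_path, seed, out_dir)
    cv, geom = _make_head(cfg)
    coil = _make_coil(cfg)
    model = surrogate.load_model(model_path)
    if pose_path:
        pose = coilmodel.CoilPose(geometry.load_transform(pose_path))
    else:
        pose = coilmodel.pose_at_site(geom, np.array([0.0, 0.0, 1.0]), 0.0,
                                      standoff_mm=cfg.coil.standoff_mm)
    vec, mag = streaming.predict_for_pose(model, geom, cv, coil, pose, cfg.fov_shape)
    geometry.save_volume_nifti(vec, out / "efield_pred.nii.gz")
    geometry.save_volume_nifti(mag, out / "efield_pred_mag.nii.gz")
    logger.info("prediction written to %s", out)


@main.command("serve")
@_common
@click.option("--model", "model_path", type=click.Path(exists=True), required=True)
def cli_serve(config_path, seed, out_dir, model_path) -> None:
    """Serve pose->image rounds over TCP (one client, n_runs rounds)."""
    import socket

    from . import streaming, surrogate

    cfg, out = _setup(config_path, seed, out_dir)
    cv, geom = _make_head(cfg)
    coil = _make_coil(cfg)
    model = surrogate.load_model(model_path)
    srv = socket.create_server((cfg.server.host, cfg.server.port))
    logger.info("listening on %s:%d", cfg.server.host, cfg.server.port)
    conn, addr = srv.accept()
    logger.info("client %s connected", addr)
    transport = streaming.TcpTransport(conn)
    stats = streaming.run_server_loop(model, geom, cv, coil, transport,
                                      cfg.server.n_runs, fov_shape=cfg.fov_shape)
    (out / "session_stats.json").write_text(json.dumps(stats.runs, indent=2))
    transport.close()
    srv.close()


@main.command("client-demo")
@_common
@click.option("--runs", type=int, default=5)
def cli_client_demo(config_path, seed, out_dir, runs) -> None:
    """Connect to a running server and stream a few demo poses."""
    from . import coilmodel, streaming

    cfg, out = _setup(config_path, seed, out_dir)
    _, geom = _make_head(cfg)
    transport = streaming.TcpTransport.connect(cfg.server.host, cfg.server.port)
    rng = np.random.default_rng(cfg.seed)
    for i in range(runs):
        u = rng.standard_normal(3)
        u[2] = abs(u[2])
        u /= np.linalg.norm(u)
        pose = coilmodel.pose_at_site(geom, u, float(rng.uniform(0, 360)),
                                      standoff_mm=cfg.coil.standoff_mm)
        img = streaming.client_request(transport, pose)
        logger.info("run %d: peak |E| %.3f V/m", i, float(img.values.max()))
    transport.close()


@main.command("benchmark")
@_common
@click.option("--runs", type=int, default=50)
def cli_benchmark(config_path, seed, out_dir, runs) -> None:
    """Time the in-process prediction loop over n runs (CNN/Vis split)."""
    from . import coilmodel, evaluation, fieldsolver, streaming, surrogate

    cfg, out = _setup(config_path, seed, out_dir)
    cv, geom = _make_head(cfg)
    coil = _make_coil(cfg)
    # a tiny surrogate is enough to time the loop machinery
    ps = coilmodel.sample_placements(geom, n_cases=2, n_directions=4,
                                     seed=cfg.placements.seed)
    samples = fieldsolver.make_dataset(geom, cv, coil, ps, fov_shape=cfg.fov_shape,
                                       tol=cfg.solver.tol)
    model = surrogate.train_surrogate(
        samples, surrogate.SurrogateConfig(epochs=1, seed=cfg.train.seed,
                                           base_channels=cfg.train.base_channels))
    server_t, client_t = streaming.loopback_pair()
    rng = np.random.default_rng(cfg.seed)
    for _ in range(runs):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        pose = coilmodel.pose_at_site(geom, u, float(rng.uniform(0, 360)))
        client_t.send(streaming.encode_message("TRANSFORM", pose))
    stats = streaming.run_server_loop(model, geom, cv, coil, server_t, runs,
                                      fov_shape=cfg.fov_shape)
    summary = evaluation.time_pipeline(stats, runs=runs)
    (out / "timing_summary.json").write_text(json.dumps(summary.as_dict(), indent=2))
    logger.info("cnn %.4f±%.4f s, vis %.4f±%.4f s over %d runs",
                summary.cnn_mean, summary.cnn_std,
                summary.vis_mean, summary.vis_std, runs)


@main.command("reproduce-table2")
@_common
def cli_reproduce_table2(config_path, seed, out_dir) -> None:
    """Recompute the packaged benchmark comparison (report as CSV + text)."""
    from . import evaluation

    _, out = _setup(config_path, seed, out_dir)
    report = evaluation.reproduce_table2()
    csv_path, txt_path = evaluation.write_report(report, out)
    click.echo(txt_path.read_text().rstrip())
    logger.info("report written to %s and %s", csv_path, txt_path)


@main.command("demo")
@_common
def cli_demo(config_path, seed, out_dir) -> None:
    """End-to-end smoke run: tiny head -> placements -> solve -> train -> serve."""
    from . import coilmodel, evaluation, fieldsolver, geometry, headmodel, \
        streaming, surrogate

    cfg, out = _setup(config_path, seed, out_dir)
    # deliberately tiny configuration, minutes on one core
    cv, geom = headmodel.make_sphere_head(outer_radius_mm=40.0,
                                          grid_shape=(24, 24, 24), voxel_mm=4.0)
    coil = _make_coil(cfg)
    ps = coilmodel.sample_placements(geom, n_cases=12, n_directions=6,
                                     seed=cfg.placements.seed)
    fov = (16, 16, 16)
    samples = fieldsolver.make_dataset(geom, cv, coil, ps, fov_shape=fov, tol=1e-7)
    fieldsolver.save_dataset(samples, out / "dataset.h5")
    model = surrogate.train_surrogate(
        samples, surrogate.SurrogateConfig(epochs=60, base_channels=8,
                                           seed=cfg.train.seed))
    surrogate.save_model(model, out / "surrogate.npz")
    report = surrogate.evaluate(model, samples)
    logger.info("train-set NE %.3f ± %.3f", report.mean, report.std)

    server_t, client_t = streaming.loopback_pair()
    for pose in ps.poses[:5]:
        client_t.send(streaming.encode_message("TRANSFORM", pose))
    stats = streaming.run_server_loop(model, geom, cv, coil, server_t, 5,
                                      fov_shape=fov)
    summary = evaluation.time_pipeline(stats, runs=5)
    (out / "timing_summary.json").write_text(json.dumps(summary.as_dict(), indent=2))

    bench = evaluation.reproduce_table2()
    evaluation.write_report(bench, out)
    fibers = headmodel.make_synthetic_streamlines(geom, n=20, seed=cfg.head.seed)
    geometry.save_streamlines(fibers, out / "fibers.trk")
    mags = [float(np.linalg.norm(s.target, axis=-1).max()) for s in samples]
    (out / "demo_summary.json").write_text(json.dumps({
        "n_cases": len(samples),
        "train_ne_mean": report.mean,
        "peak_E_Vpm": max(mags),
        "cnn_mean_s": summary.cnn_mean,
        "vis_mean_s": summary.vis_mean,
        "benchmark_t": bench["t_statistic"],
    }, indent=2))
    logger.info("demo artifacts in %s", out)


if __name__ == "__main__":
    sys.exit(main())
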