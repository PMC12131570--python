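"""Predicted-versus-ground-truth soundness evaluation on synthetic scenes.

For each pipeline this harness generates many scenes with varied generative
parameters, runs the pipeline, and scores predictions against the scene
ground truth with the coefficient of determination R^2 — the same style of
soundness evaluation used to validate trait pipelines against manual
measurements in the field.

Scene sizes here are moderate (a few hundred pixels on a side) so that a
hundred scenes per pipeline remain cheap; the generators accept larger specs
when fidelity to a particular capture setup matters more than throughput.
"""

from __future__ import annotations

import numpy as np

from .geometry import KeypointTriple
from .pipelines import (
    PipelineConfig,
    run_canopy_pheno,
    run_corn_pheno,
    run_leaf_angle,
    run_seed_pheno,
    run_spikelet_pheno,
    run_tomato_pheno,
    run_wheat_head,
)
from .synth import (
    CanopySpec,
    CornLatticeSpec,
    SeedTraySpec,
    SpikeletEarSpec,
    TomatoSceneSpec,
    WheatPlotSpec,
    gen_canopy,
    gen_corn_lattice,
    gen_seed_tray,
    gen_spikelet_ear,
    gen_tomato_scene,
    gen_wheat_plot,
    r_squared,
)

__all__ = ["run_soundness", "SOUNDNESS_KINDS"]

SOUNDNESS_KINDS = (
    "seed", "tomato", "spikelet", "canopy", "corn", "leaf_angle", "wheat_head",
)


def _scene_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _soundness_seed(n_scenes, seed):
    rng = np.random.default_rng(seed)
    pairs = {"count": ([], []), "mean_length_px": ([], [])}
    cfg = PipelineConfig()
    for s in _scene_seeds(seed, n_scenes):
        n = int(rng.integers(10, 41))
        spec = SeedTraySpec(
            n_seeds=n, height=520, width=720, coin_radius_px=70.0,
            semi_major_range=(10.0, 18.0), seed=int(s),
        )
        img, gt = gen_seed_tray(spec)
        res = run_seed_pheno(img, cfg)
        pairs["count"][0].append(res.traits["count"])
        pairs["count"][1].append(gt["count"])
        pairs["mean_length_px"][0].append(res.traits["mean"].get("length_px", 0.0))
        pairs["mean_length_px"][1].append(gt["mean_length_px"])
    return pairs


def _soundness_tomato(n_scenes, seed):
    rng = np.random.default_rng(seed)
    pairs = {"count": ([], []), "mean_diameter_px": ([], [])}
    cfg = PipelineConfig()
    for s in _scene_seeds(seed, n_scenes):
        n = int(rng.integers(4, 11))
        spec = TomatoSceneSpec(
            n_tomatoes=n, height=520, width=720, radius_range=(30.0, 55.0),
            coin_radius_px=60.0, seed=int(s),
        )
        img, gt = gen_tomato_scene(spec)
        res = run_tomato_pheno(img, cfg)
        pairs["count"][0].append(res.traits["count"])
        pairs["count"][1].append(gt["count"])
        pairs["mean_diameter_px"][0].append(
            res.traits["mean"].get("equivalent_diameter_px", 0.0)
        )
        pairs["mean_diameter_px"][1].append(gt["mean_diameter_px"])
    return pairs


def _soundness_spikelet(n_scenes, seed):
    rng = np.random.default_rng(seed)
    pairs = {"count": ([], []), "median_angle_deg": ([], [])}
    cfg = PipelineConfig()
    for s in _scene_seeds(seed, n_scenes):
        n = int(rng.integers(10, 17))
        angle = float(rng.uniform(20.0, 50.0))
        spec = SpikeletEarSpec(
            n_spikelets=n, height=700, width=520,
            angle_to_tangent_deg=angle, seed=int(s),
        )
        img, gt = gen_spikelet_ear(spec)
        res = run_spikelet_pheno(img, cfg)
        pairs["count"][0].append(res.traits["count"])
        pairs["count"][1].append(gt["count"])
        pairs["median_angle_deg"][0].append(
            res.traits.get("median_spikelet_angle_deg", 0.0)
        )
        pairs["median_angle_deg"][1].append(gt["angle_to_tangent_deg"])
    return pairs


def _soundness_canopy(n_scenes, seed):
    rng = np.random.default_rng(seed)
    pairs = {"area_px2": ([], []), "green_ratio": ([], [])}
    cfg = PipelineConfig()
    shapes = ("disc", "star", "blob")
    for i, s in enumerate(_scene_seeds(seed, n_scenes)):
        spec = CanopySpec(
            shape=shapes[i % 3],
            radius=float(rng.uniform(90.0, 160.0)),
            height=440, width=440,
            green_fraction=float(rng.uniform(0.2, 0.85)),
            seed=int(s),
        )
        img, gt = gen_canopy(spec)
        res = run_canopy_pheno(img, cfg)
        pairs["area_px2"][0].append(res.traits.get("area_px2", 0.0))
        pairs["area_px2"][1].append(gt["area_px"])
        pairs["green_ratio"][0].append(res.traits.get("green_ratio", 0.0))
        pairs["green_ratio"][1].append(gt["green_fraction"])
    return pairs


def _soundness_corn(n_scenes, seed):
    rng = np.random.default_rng(seed)
    pairs = {"row_count": ([], []), "kernel_count": ([], [])}
    cfg = PipelineConfig()
    row_choices = (8, 10, 12, 14, 16, 18)
    for i, s in enumerate(_scene_seeds(seed, n_scenes)):
        spec = CornLatticeSpec(
            rows=row_choices[i % len(row_choices)],
            cols=int(rng.integers(20, 31)),
            seed=int(s),
        )
        _, gt = gen_corn_lattice(spec)
        res = run_corn_pheno(np.asarray(gt["points"]), cfg)
        pairs["row_count"][0].append(res.traits["visible_row_count"])
        pairs["row_count"][1].append(gt["rows"])
        pairs["kernel_count"][0].append(res.traits["visible_kernel_count"])
        pairs["kernel_count"][1].append(gt["count"])
    return pairs


def _soundness_leaf_angle(n_scenes, seed):
    rng = np.random.default_rng(seed)
    pairs = {"angle_deg": ([], [])}
    cfg = PipelineConfig()
    for _ in range(n_scenes):
        angle = float(rng.uniform(5.0, 120.0))
        stem_dir = rng.uniform(0, 2 * np.pi)
        c = rng.uniform(100, 400, size=2)
        b = c + 180.0 * np.asarray([np.cos(stem_dir), np.sin(stem_dir)])
        a = c - 150.0 * np.asarray([np.cos(stem_dir), np.sin(stem_dir)])
        leaf_dir = stem_dir + np.radians(angle)
        ell = c + 120.0 * np.asarray([np.cos(leaf_dir), np.sin(leaf_dir)])
        k = KeypointTriple(A=tuple(a), B=tuple(b), C=tuple(c), L=tuple(ell))
        res = run_leaf_angle(k, cfg)
        pairs["angle_deg"][0].append(res.traits["flag_leaf_angle_deg"])
        pairs["angle_deg"][1].append(angle)
    return pairs


def _soundness_wheat(n_scenes, seed):
    rng = np.random.default_rng(seed)
    pairs = {"density_per_m2": ([], []), "count": ([], [])}
    cfg = PipelineConfig()
    for s in _scene_seeds(seed, n_scenes):
        spec = WheatPlotSpec(
            height=680, width=840, marker_px_w=480.0,
            density_per_m2=float(rng.integers(25, 91)), seed=int(s),
        )
        img, gt = gen_wheat_plot(spec)
        res = run_wheat_head(img, cfg)
        pairs["density_per_m2"][0].append(res.traits.get("density_per_m2", 0.0))
        pairs["density_per_m2"][1].append(gt["density_per_m2"])
        pairs["count"][0].append(res.traits["count"])
        pairs["count"][1].append(gt["inside_count"])
    return pairs


_RUNNERS = {
    "seed": _soundness_seed,
    "tomato": _soundness_tomato,
    "spikelet": _soundness_spikelet,
    "canopy": _soundness_canopy,
    "corn": _soundness_corn,
    "leaf_angle": _soundness_leaf_angle,
    "wheat_head": _soundness_wheat,
}


def run_soundness(kind: str, n_scenes: int = 100, seed: int = 0) -> dict:
    """R^2 of pipeline predictions against ground truth over many scenes.

    Returns ``{trait: {"r2": float, "predicted": list, "reference": list}}``.
    """
    if kind not in _RUNNERS:
        raise ValueError(f"unknown soundness kind {kind!r}; one of {SOUNDNESS_KINDS}")
    pairs = _RUNNERS[kind](n_scenes, seed)
    out = {}
    for trait, (pred, ref) in pairs.items():
        out[trait] = {
            "r2": r_squared(pred, ref),
            "predicted": [float(v) for v in pred],
            "reference": [float(v) for v in ref],
        }
    return out
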