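"""Synthetic adipose-tissue generator.

Produces ground-truth-labelled two-channel 3D stacks that emulate cleared
adipose tissue imaged on a confocal microscope:

* **in situ** — space-filling, convex-ish polyhedral cells separated by
  extracellular-matrix (ECM) walls, built as a power-weighted (Laguerre)
  Voronoi tessellation of collision-relaxed sphere seeds. Neighbouring
  cells share flat facets, which gives the angular outlines and reduced
  sphericity of cells constrained by tissue.
* **ex situ** — sparse, non-touching digitized spheres, emulating freshly
  extracted adipocytes floating free of their matrix.

Rendered channels follow the staining scheme of the emulated experiments:
channel 0 is a bright ECM shell around every cell boundary (5-DTAF-like),
channel 1 a uniform lipid interior (Nile-red-like). Both decay
exponentially with imaging depth z (attenuation length = clearing quality)
and carry additive Gaussian detector noise over a constant background.

Every operation is a pure function of its inputs and an integer seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import __version__
from .errors import GeometryError, ParameterError
from .morphometry import measure_regions, save_cell_table
from .presets import CohortDesign, TissuePreset, _lognormal_params
from .stacks import DEFAULT_SPACING, ImageStack, LabelStack

# Rendered signal amplitudes (arbitrary intensity units, uint16 on disk).
ECM_INTENSITY = 120.0
LIPID_INTENSITY = 100.0

#: Fraction of the seed-sphere radius sum by which neighbouring seeds may
#: overlap after relaxation. Overlaps become the shared flat facets of the
#: tessellation; 0.10 trades angularity against cell-volume fidelity.
OVERLAP_ALLOWANCE = 0.10

#: Default fill fraction (total target cell volume / domain volume) used
#: when auto-sizing a stack for a requested cell count.
IN_SITU_FILL = 0.50
EX_SITU_FILL = 0.15


def sample_diameters(preset: TissuePreset, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` cell diameters (µm) from the preset's distribution.

    The lognormal is parameterized so that its *arithmetic* mean equals
    ``diameter_mean`` and its coefficient of variation ``diameter_cv``
    (µ = ln m − σ²/2, σ² = ln(1+cv²)), so generated samples are directly
    comparable with published depot means. Mixture presets draw the
    component of each cell first, then its diameter.
    """
    if n < 0:
        raise ParameterError("n must be >= 0")
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty(0)
    if preset.mixture is not None:
        weights = np.array([w for w, _, _ in preset.mixture])
        comps = rng.choice(len(weights), size=n, p=weights)
        out = np.empty(n)
        for k, (_, m, cv) in enumerate(preset.mixture):
            mu, sigma = _lognormal_params(m, cv)
            sel = comps == k
            out[sel] = rng.lognormal(mu, sigma, int(sel.sum()))
        return out
    mu, sigma = _lognormal_params(preset.diameter_mean, preset.diameter_cv)
    return rng.lognormal(mu, sigma, n)


def _check_fit(radii, extent, spacing):
    margin = max(spacing)
    if radii.size and 2 * radii.max() + 2 * margin > min(extent):
        raise GeometryError(
            f"stack extent {tuple(np.round(extent, 1))} µm cannot contain a "
            f"cell of diameter {2 * radii.max():.1f} µm"
        )


def _relax_centers(centers, radii, lo, hi, rng, max_iter=300):
    """Push overlapping seed spheres apart until every pair is separated by
    at least (1 − OVERLAP_ALLOWANCE)·(r_i + r_j), keeping centers in box."""
    n = len(centers)
    if n < 2:
        return centers
    target = (1.0 - OVERLAP_ALLOWANCE) * np.add.outer(radii, radii)
    np.fill_diagonal(target, 0.0)
    for _ in range(max_iter):
        diff = centers[:, None, :] - centers[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        deficit = target - dist
        if deficit.max() <= 1e-9:
            break
        ii, jj = np.nonzero(np.triu(deficit > 1e-9, 1))
        shift = np.zeros_like(centers)
        for i, j in zip(ii, jj):
            d = dist[i, j]
            if d < 1e-9:
                direction = rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
            else:
                direction = diff[i, j] / d
            step = 0.55 * deficit[i, j]
            shift[i] += step * direction
            shift[j] -= step * direction
        centers = np.clip(centers + shift, lo, hi)
    return centers


def _volume_matched_radii(centers, radii, ecm_thickness, spacing, n_iter=3):
    """Adjust clip radii so each cell's final voxel volume approximates its
    target sphere volume.

    A cell clipped by the power planes of overlapping neighbours loses the
    spherical caps beyond each plane, and the wall carve removes a slab of
    ECM thickness along every shared facet. Both losses follow from the
    relaxed geometry in closed form (cap volume πh²(3r−h)/3, slab volume ≈
    facet area × carve depth), so the radii can be inflated to compensate
    by fixed-point iteration on V(r) = V_target.
    """
    n = len(radii)
    target = (4.0 / 3.0) * np.pi * radii**3
    if n == 1:
        return radii.copy()
    # Carve depth charged to each cell of a facet pair: the one-layer carve
    # removes ~one voxel from the higher-label (later-index) side; the
    # symmetric carve removes ecm_thickness/2 from both.
    mean_sp = float(np.mean(spacing))
    one_layer = ecm_thickness <= 1.5 * max(spacing)
    diff = centers[:, None, :] - centers[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(dist, np.inf)
    r = radii.copy()
    for _ in range(n_iter):
        # distance from centre i to the power plane with each neighbour
        with np.errstate(invalid="ignore"):
            x = (dist**2 + r[:, None] ** 2 - r[None, :] ** 2) / (2.0 * dist)
        x = np.nan_to_num(x, nan=np.inf, posinf=np.inf)
        contact = dist < r[:, None] + r[None, :] + mean_sp
        h = np.clip(r[:, None] - x, 0.0, r[:, None])
        cap = np.where(contact, np.pi * h**2 * (3.0 * r[:, None] - h) / 3.0, 0.0)
        facet = np.where(contact, np.pi * np.clip(r[:, None] ** 2 - x**2, 0.0, None), 0.0)
        if one_layer and ecm_thickness > 0:
            depth = np.zeros((n, n))
            depth[np.tril_indices(n, -1)] = mean_sp  # later index carved
            carve = facet * depth
        elif ecm_thickness > 0:
            carve = facet * (ecm_thickness / 2.0)
        else:
            carve = np.zeros((n, n))
        volume = (4.0 / 3.0) * np.pi * r**3 - cap.sum(axis=1) - carve.sum(axis=1)
        r = r * np.clip(np.cbrt(target / np.clip(volume, 1e-9, None)), 0.95, 1.15)
    return r


def _wall_footprint(rad):
    """Ellipsoidal footprint with the given per-axis voxel radii."""
    rad = np.asarray(rad, dtype=int)
    zz, yy, xx = np.indices(2 * rad + 1) - rad[:, None, None, None]
    return (
        (zz / max(rad[0], 1)) ** 2
        + (yy / max(rad[1], 1)) ** 2
        + (xx / max(rad[2], 1)) ** 2
    ) <= 1.0 + 1e-9


def _carve_walls(labels: np.ndarray, thickness: float, spacing) -> None:
    """Carve an ECM gap of total ``thickness`` µm along walls between
    different cells (in place).

    When the requested wall is about one voxel wide, a symmetric carve
    (one voxel per side) would double it, so a single voxel layer is
    removed from one side of each wall instead; thicker walls are carved
    symmetrically with radius thickness/2 on each side.
    """
    spacing = np.asarray(spacing, dtype=float)
    big = np.iinfo(labels.dtype).max
    pos = np.where(labels > 0, labels, big)
    if thickness <= 1.5 * spacing.max():
        # One voxel in total: carve the face-adjacent layer on the
        # higher-id side of each wall.
        wall = np.zeros(labels.shape, dtype=bool)
        for ax in range(3):
            for shift in (-1, 1):
                nb = np.roll(pos, shift, axis=ax)
                # roll wraps around; wrapped faces compare against big
                edge = [slice(None)] * 3
                edge[ax] = slice(0, 1) if shift == 1 else slice(-1, None)
                nb[tuple(edge)] = big
                wall |= (labels > 0) & (nb != big) & (nb < labels)
    else:
        rad = np.maximum(1, np.round((thickness / 2.0) / spacing)).astype(int)
        foot = _wall_footprint(rad)
        lo_f = ndimage.minimum_filter(pos, footprint=foot)
        hi_f = ndimage.maximum_filter(labels, footprint=foot)
        wall = (labels > 0) & (hi_f != lo_f) & (lo_f != big) & (hi_f > 0)
    labels[wall] = 0


def pack_in_situ(
    diameters,
    shape,
    spacing=DEFAULT_SPACING,
    seed: int = 0,
    ecm_thickness: float = 2.3,
) -> LabelStack:
    """Tessellate the stack into space-filling polyhedral cells.

    Sphere seeds with radii from ``diameters`` are placed uniformly at
    random (entirely inside the stack), relaxed to limit pairwise overlap,
    and each voxel within a seed's radius is assigned to the seed of
    minimal power distance ‖x − c‖² − r², i.e. a Laguerre tessellation
    clipped to the union of seed spheres. Where seeds overlap, the power
    plane produces a shared flat facet. Finally an ECM gap of
    ``ecm_thickness`` is carved along walls between neighbouring cells
    (label 0 = background/ECM).
    """
    diameters = np.atleast_1d(np.asarray(diameters, dtype=float))
    if diameters.size == 0:
        raise GeometryError("at least one diameter is required")
    if np.any(diameters <= 0):
        raise ParameterError("diameters must be positive")
    shape = tuple(int(s) for s in shape)
    spacing = np.asarray(spacing, dtype=float)
    extent = np.array(shape) * spacing
    radii = diameters / 2.0
    _check_fit(radii, extent, spacing)

    rng = np.random.default_rng(seed)
    # Place large cells first so they relax into stable positions.
    order = np.argsort(radii)[::-1]
    radii = radii[order]
    # 5% radius headroom keeps volume-matched (inflated) cells inside.
    margin = max(spacing)
    lo = (1.05 * radii + margin)[:, None] * np.ones(3)
    hi = extent[None, :] - lo
    if np.any(hi <= lo):
        raise GeometryError("stack too small to contain the largest cell")
    centers = lo + rng.random((len(radii), 3)) * (hi - lo)
    centers = _relax_centers(centers, radii, lo, hi, rng)
    radii = _volume_matched_radii(centers, radii, ecm_thickness, spacing)

    labels = np.zeros(shape, dtype=np.int32)
    best_power = np.full(shape, np.inf, dtype=np.float32)
    axes = [np.arange(shape[ax]) * spacing[ax] for ax in range(3)]
    for idx in range(len(radii)):
        c, r = centers[idx], radii[idx]
        lo_v = np.maximum(0, np.floor((c - r) / spacing).astype(int))
        hi_v = np.minimum(shape, np.ceil((c + r) / spacing).astype(int) + 1)
        sl = tuple(slice(a, b) for a, b in zip(lo_v, hi_v))
        d2 = (
            (axes[0][sl[0]] - c[0])[:, None, None] ** 2
            + (axes[1][sl[1]] - c[1])[None, :, None] ** 2
            + (axes[2][sl[2]] - c[2])[None, None, :] ** 2
        ).astype(np.float32)
        power = d2 - r * r
        take = (d2 <= r * r) & (power < best_power[sl])
        labels[sl][take] = idx + 1
        best_power[sl][take] = power[take]

    if ecm_thickness > 0:
        _carve_walls(labels, ecm_thickness, spacing)

    return LabelStack(_relabel_sequential(labels), tuple(spacing))


def _relabel_sequential(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(int(ids.max()) + 1 if ids.size else 1, dtype=labels.dtype)
    lut[ids] = np.arange(1, ids.size + 1, dtype=labels.dtype)
    return lut[labels]


def pack_ex_situ(
    diameters,
    shape,
    spacing=DEFAULT_SPACING,
    seed: int = 0,
    min_gap: float | None = None,
    max_tries: int = 5000,
) -> LabelStack:
    """Place non-touching digitized spheres at random positions.

    Spheres are placed largest-first by rejection sampling; any two labels
    keep a surface gap of at least ``min_gap`` (default: two voxel
    pitches, which guarantees at least one empty voxel between digitized
    surfaces). If a
    sphere cannot be placed within ``max_tries`` attempts a
    :class:`GeometryError` reporting the number already placed is raised.
    """
    diameters = np.atleast_1d(np.asarray(diameters, dtype=float))
    if diameters.size == 0:
        raise GeometryError("at least one diameter is required")
    if np.any(diameters <= 0):
        raise ParameterError("diameters must be positive")
    shape = tuple(int(s) for s in shape)
    spacing = np.asarray(spacing, dtype=float)
    extent = np.array(shape) * spacing
    if min_gap is None:
        min_gap = 2.0 * float(max(spacing))
    order = np.argsort(diameters)[::-1]
    radii = diameters[order] / 2.0
    _check_fit(radii, extent, spacing)

    rng = np.random.default_rng(seed)
    placed_c: list[np.ndarray] = []
    placed_r: list[float] = []
    for k, r in enumerate(radii):
        lo = r + max(spacing)
        hi = extent - lo
        ok = False
        for _ in range(max_tries):
            c = lo + rng.random(3) * (hi - lo)
            if all(
                np.linalg.norm(c - pc) >= r + pr + min_gap
                for pc, pr in zip(placed_c, placed_r)
            ):
                ok = True
                break
        if not ok:
            raise GeometryError(
                f"could not place sphere {k + 1}/{len(radii)} "
                f"(diameter {2 * r:.1f} µm) without contact",
                placed=len(placed_c),
            )
        placed_c.append(c)
        placed_r.append(float(r))

    labels = np.zeros(shape, dtype=np.int32)
    axes = [np.arange(shape[ax]) * spacing[ax] for ax in range(3)]
    for idx, (c, r) in enumerate(zip(placed_c, placed_r)):
        lo_v = np.maximum(0, np.floor((c - r) / spacing).astype(int))
        hi_v = np.minimum(shape, np.ceil((c + r) / spacing).astype(int) + 1)
        sl = tuple(slice(a, b) for a, b in zip(lo_v, hi_v))
        d2 = (
            (axes[0][sl[0]] - c[0])[:, None, None] ** 2
            + (axes[1][sl[1]] - c[1])[None, :, None] ** 2
            + (axes[2][sl[2]] - c[2])[None, None, :] ** 2
        )
        labels[sl][d2 <= r * r] = idx + 1
    return LabelStack(labels, tuple(spacing))


def render_channels(labels: LabelStack, preset: TissuePreset, seed: int = 0) -> ImageStack:
    """Render a labelled geometry into fluorescence channels.

    In situ presets produce two channels: channel 0 is a bright ECM shell
    of ``ecm_thickness`` lining every cell boundary (on the background
    side, i.e. the carved walls and the rim of the tissue), channel 1 a
    uniform lipid interior. Ex situ presets produce the lipid channel
    only. Signals are multiplied by exp(−z·Δz / attenuation_length), then
    a constant background and additive Gaussian noise (clipped at zero)
    are applied.
    """
    rng = np.random.default_rng(seed)
    lab = labels.labels
    spacing = labels.spacing
    interior = lab > 0
    lipid = LIPID_INTENSITY * interior.astype(np.float64)

    channels = []
    names = []
    if preset.packing == "in_situ":
        dist_to_cell = ndimage.distance_transform_edt(~interior, sampling=spacing)
        shell = ~interior & (dist_to_cell <= max(preset.ecm_thickness, max(spacing)))
        channels.append(ECM_INTENSITY * shell.astype(np.float64))
        names.append("ecm")
    channels.append(lipid)
    names.append("lipid")

    z = np.arange(lab.shape[0]) * spacing[0]
    atten = np.exp(-z / preset.attenuation_length)[None, :, None, None]
    data = np.stack(channels) * atten
    if preset.background:
        data = data + preset.background
    if preset.noise_sd:
        data = data + rng.normal(0.0, preset.noise_sd, data.shape)
    return ImageStack(np.clip(data, 0.0, None), tuple(spacing), names)


def auto_shape(diameters, spacing, packing: str) -> tuple[int, int, int]:
    """Cube-ish stack shape whose volume hosts the cells at the default
    fill fraction of the packing mode."""
    diameters = np.asarray(diameters, dtype=float)
    fill = IN_SITU_FILL if packing == "in_situ" else EX_SITU_FILL
    total = (np.pi / 6.0) * (diameters**3).sum()
    side = (total / fill) ** (1.0 / 3.0)
    side = max(side, 1.2 * diameters.max() if diameters.size else side)
    shape = tuple(int(np.ceil(side / s)) + 2 for s in spacing)
    return shape


def generate_sample(spec, spacing=DEFAULT_SPACING):
    """Generate one sample: (diameters, LabelStack, ImageStack, CellTable).

    Child random streams (diameter sampling, packing, rendering) are
    derived deterministically from the sample's master seed.
    """
    seeds = np.random.SeedSequence(spec.seed).generate_state(3)
    diameters = sample_diameters(spec.preset, spec.n_cells_target, int(seeds[0]))
    shape = spec.shape or auto_shape(diameters, spacing, spec.preset.packing)
    if spec.preset.packing == "in_situ":
        truth = pack_in_situ(
            diameters, shape, spacing, int(seeds[1]),
            ecm_thickness=spec.preset.ecm_thickness,
        )
    else:
        truth = pack_ex_situ(diameters, shape, spacing, int(seeds[1]))
    stack = render_channels(truth, spec.preset, int(seeds[2]))
    table = measure_regions(
        truth,
        metadata=dict(
            sample_id=spec.sample_id,
            tissue=spec.tissue,
            condition=spec.condition,
            sex=spec.sex,
            body_weight=spec.body_weight,
        ),
    )
    return diameters, truth, stack, table


def generate_cohort(design: CohortDesign, out_dir, spacing=DEFAULT_SPACING) -> dict:
    """Generate every sample of a cohort and write it to ``out_dir``.

    For each sample the rendered stack, the ground-truth label stack and
    the ground-truth cell table are written; a JSON manifest records
    seeds, presets, spacing and file paths. Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "spacing_um": list(spacing),
        "axis_order": "ZYX",
        "samples": [],
    }
    for spec in design:
        _, truth, stack, table = generate_sample(spec, spacing)
        base = out_dir / spec.sample_id
        stack_path = base.with_name(base.name + "_stack.tif")
        labels_path = base.with_name(base.name + "_truth_labels.tif")
        table_path = base.with_name(base.name + "_truth_cells.csv")
        stack.save(stack_path)
        truth.save(labels_path)
        save_cell_table(table_path, table)
        manifest["samples"].append(
            {
                "sample_id": spec.sample_id,
                "subject_id": spec.subject_id,
                "tissue": spec.tissue,
                "condition": spec.condition,
                "sex": spec.sex,
                "body_weight_g": spec.body_weight,
                "seed": spec.seed,
                "n_cells_target": spec.n_cells_target,
                "preset": dataclasses.asdict(spec.preset),
                "stack": stack_path.name,
                "truth_labels": labels_path.name,
                "truth_cells": table_path.name,
                "channel_names": stack.channel_names,
            }
        )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
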