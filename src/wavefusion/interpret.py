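"""Localization outputs: attention weights, scalp topomaps, class maps.

The per-lead attention weights produced at inference are interpolated
over the unit-disk scalp to visualize which recording sites drive the
prediction.  Per-lead class activation maps are computed with a
gradient-weighted scheme at the last spatially extended CNN stage (the
second convolution's 4 x 4 activation): the final convolutional output of
each lightweight CNN is a 1 x 1 map with no spatial extent, so the
classic global-average-pooling CAM is degenerate here and the
gradient-weighted variant at the 4 x 4 stage is the only spatially
meaningful choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.ndimage import zoom

from .model import WaveFusionNet
from .montage import Montage

logger = logging.getLogger(__name__)


@dataclass
class TopoMap:
    """Interpolated attention surface over the unit-disk scalp."""

    grid: np.ndarray          # (res, res), NaN outside the disk
    xs: np.ndarray            # grid x coordinates
    ys: np.ndarray            # grid y coordinates
    coords: np.ndarray        # (n_leads, 2) electrode positions
    values: np.ndarray        # (n_leads,) attention at the electrodes
    lead_names: tuple[str, ...]


@dataclass
class CamMap:
    """Max-normalized class activation heat map for one (lead, class)."""

    heat: np.ndarray          # (freq, time) in [0, 1]
    lead: str
    class_label: int


def extract_attention(net: WaveFusionNet, sample: np.ndarray,
                      lead_names: tuple[str, ...] | None = None
                      ) -> dict[str, float]:
    """Attention weights of one sample, keyed by lead name.

    With the attention module disabled the weights are identically 1.
    """
    X = np.asarray(sample, dtype=float)
    if X.ndim == 3:
        X = X[None]
    _, cache = net.encode(X, train=False)
    pi = cache["pi"][0]
    if lead_names is None:
        lead_names = tuple(f"lead{i}" for i in range(len(pi)))
    return {name: float(p) for name, p in zip(lead_names, pi)}


def interpolate_topomap(pi: dict[str, float] | np.ndarray,
                        montage: Montage, resolution: int = 64,
                        method: str = "thin_plate") -> TopoMap:
    """Interpolate per-lead weights onto the scalp disk.

    Radial-basis interpolation (thin-plate spline by default, ``linear``
    as an option), exact at the electrode positions, masked and clipped to
    the observed value range outside them.
    """
    if isinstance(pi, dict):
        names = tuple(pi)
        values = np.array([pi[n] for n in names], dtype=float)
        coords = montage.subset(names).coords
    else:
        values = np.asarray(pi, dtype=float)
        names = montage.lead_names
        coords = montage.coords
        if len(values) != len(coords):
            raise ValueError("one weight per montage lead required")
    if len(np.unique(coords.round(9), axis=0)) != len(coords):
        raise ValueError("duplicate electrode coordinates in montage")
    kernel = {"thin_plate": "thin_plate_spline", "linear": "linear"}[method]
    interp = RBFInterpolator(coords, values, kernel=kernel)
    xs = np.linspace(-1, 1, resolution)
    ys = np.linspace(-1, 1, resolution)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    grid = interp(pts).reshape(resolution, resolution)
    grid = np.clip(grid, values.min(), values.max())
    grid[gx ** 2 + gy ** 2 > 1.0] = np.nan
    return TopoMap(grid=grid, xs=xs, ys=ys, coords=coords, values=values,
                   lead_names=names)


def topomap_value_at(topo: TopoMap, x: float, y: float,
                     montage: Montage | None = None,
                     method: str = "thin_plate") -> float:
    """Evaluate the interpolant at an arbitrary scalp point."""
    kernel = {"thin_plate": "thin_plate_spline", "linear": "linear"}[method]
    interp = RBFInterpolator(topo.coords, topo.values, kernel=kernel)
    val = float(interp(np.array([[x, y]]))[0])
    return float(np.clip(val, topo.values.min(), topo.values.max()))


def class_activation_map(net: WaveFusionNet, sample: np.ndarray,
                         lead: int | str, class_label: int,
                         lead_names: tuple[str, ...] | None = None
                         ) -> CamMap:
    """Gradient-weighted class activation map for one lead and class.

    Channel weights are the spatial means of the class logit's gradient at
    the second conv stage; the weighted activation sum is rectified,
    bilinearly upsampled to the spectrogram shape and max-normalized.
    """
    X = np.asarray(sample, dtype=float)
    if X.ndim == 3:
        X = X[None]
    if isinstance(lead, str):
        if lead_names is None:
            raise ValueError("lead_names required to resolve a lead name")
        lead_idx = lead_names.index(lead)
        lead_label = lead
    else:
        lead_idx = int(lead)
        lead_label = (lead_names[lead_idx] if lead_names
                      else f"lead{lead_idx}")
    logits, cache = net.forward_logits(X, train=False)
    net.zero_grad()
    dlogits = np.zeros_like(logits)
    dlogits[0, class_label] = 1.0
    net.backward_from_logits(dlogits, cache)
    act = net.cam_activation[0, lead_idx]       # (C, h, w)
    grad = net.cam_gradient[0, lead_idx]
    weights = grad.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * act).sum(axis=0), 0.0)
    f, t = net.config.input_shape
    heat = zoom(cam, (f / cam.shape[0], t / cam.shape[1]), order=1,
                grid_mode=True, mode="nearest")
    heat = np.maximum(heat, 0.0)
    peak = heat.max()
    if peak == 0:
        logger.warning("class activation map is identically zero for lead "
                       "%s, class %d", lead_label, class_label)
        return CamMap(heat=heat, lead=lead_label, class_label=class_label)
    return CamMap(heat=heat / peak, lead=lead_label, class_label=class_label)


# ---------------------------------------------------------------------- #
# figure and numeric export


def save_topomap_figure(topo: TopoMap, path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.pcolormesh(topo.xs, topo.ys, topo.grid, shading="auto",
                       cmap="RdBu_r")
    ax.scatter(topo.coords[:, 0], topo.coords[:, 1], s=8, c="k")
    circle = plt.Circle((0, 0), 1.0, fill=False, color="k", lw=1)
    ax.add_patch(circle)
    ax.set_aspect("equal")
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8, label="attention weight")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def save_cam_figure(cams: list[CamMap], path,
                    freq_centers=None, time_centers=None) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(cams), figsize=(3 * len(cams), 3),
                             squeeze=False)
    extent = None
    if freq_centers is not None and time_centers is not None:
        extent = (time_centers[0], time_centers[-1],
                  freq_centers[0], freq_centers[-1])
    for ax, cam in zip(axes[0], cams):
        ax.imshow(cam.heat, origin="lower", aspect="auto", cmap="inferno",
                  extent=extent, vmin=0, vmax=1)
        ax.set_title(f"{cam.lead} / class {cam.class_label}", fontsize=9)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("frequency (Hz)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def export_attention_csv(pi: dict[str, float], path) -> None:
    import pandas as pd
    pd.DataFrame({"lead_name": list(pi), "attention": list(pi.values())}
                 ).to_csv(path, index=False)


def export_cam_arrays(cams: list[CamMap], path) -> None:
    arrays = {f"{c.lead}_class{c.class_label}": c.heat for c in cams}
    np.savez_compressed(path, **arrays)
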