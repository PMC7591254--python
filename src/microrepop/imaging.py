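"""Immunofluorescence quantification: segmentation, colocalization, counting.

Each channel is segmented by an adaptive (local-mean) threshold and
8-connected labelling; cells positive for two markers are called when their
masks overlap by strictly more than 10% of the smaller mask; phenotype
counts and per-cell mean intensities follow from the anchor (IBA1) objects.
A synthetic renderer plants disk-shaped cells with known phenotypes so the
whole chain is checkable against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.measure import label as cc_label, regionprops


@dataclass
class ChannelStack:
    """Same-shape 2-D intensity images keyed by channel name."""

    channels: dict[str, np.ndarray]
    pixel_size: float = 1.0  # microns per pixel

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("channels must share one shape")
        for name, ch in self.channels.items():
            if (ch < 0).any():
                raise ValueError(f"negative intensities in channel {name!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class LabelImage:
    """Integer-labelled segmentation (0 = background) with an object table."""

    labels: np.ndarray
    objects: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def areas(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=self.n_objects + 1)[1:]


def synth_image(
    n_cells_per_phenotype: dict[str, int],
    phenotype_channels: dict[str, dict[str, float]],
    shape: tuple[int, int] = (512, 512),
    radius: int = 6,
    noise_sd: float = 0.0,
    min_separation: float | None = None,
    seed: int = 0,
    max_tries: int = 20_000,
) -> tuple[ChannelStack, pd.DataFrame]:
    """Render disk cells of known phenotype into a multi-channel field.

    ``phenotype_channels`` maps phenotype -> {channel: intensity}; a cell
    paints a disk of ``radius`` into each channel its phenotype names.
    Centres are placed by rejection sampling at ``min_separation`` (default
    2.5 radii) so planted masks do not merge. Gaussian noise of
    ``noise_sd`` is added (clipped at zero). Returns the stack and a truth
    table (cell id, phenotype, row, col, radius).
    """
    rng = np.random.default_rng(seed)
    sep = 2.5 * radius if min_separation is None else min_separation
    channel_names = sorted({c for chans in phenotype_channels.values() for c in chans})
    images = {c: np.zeros(shape, dtype=np.float64) for c in channel_names}

    centers: list[tuple[float, float]] = []
    rows = []
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    cell_id = 0
    for phenotype, n in n_cells_per_phenotype.items():
        if phenotype not in phenotype_channels:
            raise ValueError(f"unknown phenotype {phenotype!r}")
        for _ in range(n):
            for attempt in range(max_tries):
                r = rng.uniform(radius + 1, shape[0] - radius - 1)
                c = rng.uniform(radius + 1, shape[1] - radius - 1)
                if all((r - r0) ** 2 + (c - c0) ** 2 >= sep**2 for r0, c0 in centers):
                    break
            else:
                raise RuntimeError(
                    "could not place cells at the requested density"
                )
            centers.append((r, c))
            disk = (yy - r) ** 2 + (xx - c) ** 2 <= radius**2
            for chan, intensity in phenotype_channels[phenotype].items():
                images[chan][disk] = intensity
            rows.append((cell_id, phenotype, r, c, radius))
            cell_id += 1
    if noise_sd > 0:
        for chan in images:
            images[chan] = np.clip(
                images[chan] + rng.normal(0.0, noise_sd, shape), 0.0, None
            )
    truth = pd.DataFrame(rows, columns=["cell_id", "phenotype", "row", "col", "radius"])
    return ChannelStack(channels=images), truth


def adaptive_threshold(
    image: np.ndarray, window: int = 51, offset: float = 0.0
) -> np.ndarray:
    """Foreground where intensity exceeds the local mean (window) plus offset."""
    image = np.asarray(image, dtype=np.float64)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window > min(image.shape):
        raise ValueError("window larger than image")
    local_mean = ndi.uniform_filter(image, size=window, mode="reflect")
    return image > local_mean + offset


def segment(mask: np.ndarray, min_size: int = 30) -> LabelImage:
    """8-connected components of a binary mask, small objects dropped."""
    labels = cc_label(np.asarray(mask, dtype=bool), connectivity=2)
    if labels.max() == 0:
        return LabelImage(labels=labels, objects=pd.DataFrame(
            columns=["label", "area", "centroid_row", "centroid_col"]))
    areas = np.bincount(labels.ravel())
    keep = np.flatnonzero(areas >= min_size)
    keep = keep[keep > 0]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    labels = remap[labels]
    rows = [
        (p.label, p.area, p.centroid[0], p.centroid[1])
        for p in regionprops(labels)
    ]
    return LabelImage(
        labels=labels,
        objects=pd.DataFrame(rows, columns=["label", "area", "centroid_row", "centroid_col"]),
    )


def colocalize(
    a: LabelImage, b: LabelImage, min_overlap: float = 0.10
) -> pd.DataFrame:
    """One-to-one object pairs whose masks overlap > ``min_overlap``.

    The overlap fraction is intersection area over the smaller of the two
    masks (a symmetric rule). Each object pairs with at most one partner;
    competing candidates are resolved by largest intersection, ties by
    lower label id. Returns columns (label_a, label_b, n_pixels, fraction).
    """
    if a.labels.shape != b.labels.shape:
        raise ValueError("label images must share shape")
    la = a.labels.ravel()
    lb = b.labels.ravel()
    both = (la > 0) & (lb > 0)
    cols = ["label_a", "label_b", "n_pixels", "fraction"]
    if not both.any():
        return pd.DataFrame(columns=cols)
    nb = int(lb.max())
    pair_codes = la[both].astype(np.int64) * (nb + 1) + lb[both]
    codes, inter = np.unique(pair_codes, return_counts=True)
    pa = (codes // (nb + 1)).astype(int)
    pb = (codes % (nb + 1)).astype(int)
    area_a = a.areas()
    area_b = b.areas()
    frac = inter / np.minimum(area_a[pa - 1], area_b[pb - 1])
    ok = frac > min_overlap  # strict: exactly 10% is excluded
    cand = sorted(
        zip(pa[ok], pb[ok], inter[ok], frac[ok]),
        key=lambda t: (-t[2], t[0], t[1]),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    rows = []
    for la_, lb_, n_, f_ in cand:
        if la_ in used_a or lb_ in used_b:
            continue
        used_a.add(la_)
        used_b.add(lb_)
        rows.append((int(la_), int(lb_), int(n_), float(f_)))
    return pd.DataFrame(rows, columns=cols)


def count_phenotypes(
    channel_labels: dict[str, LabelImage],
    anchor: str = "IBA1",
    min_overlap: float = 0.10,
) -> pd.DataFrame:
    """Classify anchor objects by which other markers colocalize with them.

    Returns one row per phenotype combination (e.g. ``IBA1+MAC2+EdU-``)
    with counts; counts partition the anchor objects. Percentages against
    the anchor denominator are in ``pct_of_anchor``.
    """
    if anchor not in channel_labels:
        raise ValueError(f"missing anchor channel {anchor!r}")
    anchor_img = channel_labels[anchor]
    n_anchor = anchor_img.n_objects
    markers = [m for m in channel_labels if m != anchor]
    positive = {}
    for m in markers:
        pairs = colocalize(anchor_img, channel_labels[m], min_overlap=min_overlap)
        positive[m] = set(pairs["label_a"].tolist())
    combos: dict[str, int] = {}
    for obj in range(1, n_anchor + 1):
        name = f"{anchor}+" + "".join(
            f"{m}{'+' if obj in positive[m] else '-'}" for m in markers
        )
        combos[name] = combos.get(name, 0) + 1
    out = pd.DataFrame(
        sorted(combos.items()), columns=["phenotype", "count"]
    )
    out["pct_of_anchor"] = 100.0 * out["count"] / max(n_anchor, 1)
    return out


def marker_fraction(counts: pd.DataFrame, marker: str) -> float:
    """Percent of anchor objects positive for ``marker`` (e.g. 'MAC2')."""
    pos = counts.loc[counts["phenotype"].str.contains(f"{marker}\\+"), "count"].sum()
    total = counts["count"].sum()
    return 100.0 * pos / max(total, 1)


def mean_intensity_per_object(
    intensity_channel: np.ndarray, anchor: LabelImage
) -> pd.DataFrame:
    """Mean channel intensity over each anchor object's pixels."""
    if intensity_channel.shape != anchor.labels.shape:
        raise ValueError("shapes must match")
    n = anchor.n_objects
    if n == 0:
        return pd.DataFrame(columns=["label", "mean_intensity"])
    means = ndi.mean(intensity_channel, labels=anchor.labels, index=np.arange(1, n + 1))
    return pd.DataFrame({"label": np.arange(1, n + 1), "mean_intensity": means})
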