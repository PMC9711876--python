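"""Quantitative brightfield IHC: optical density, stain unmixing,
compartment segmentation, and intensity summaries.

The physical model is Beer-Lambert absorbance: a pixel with transmitted
intensity I against white reference I0 has optical density
OD = -log10(I / I0) per RGB channel, and the OD vector is (approximately)
a non-negative combination of per-stain unit colour vectors. Least-squares
unmixing in OD space yields per-stain concentration maps; compartment means
of the chromogen (e.g. DAB) map give the continuous readouts used
downstream: nuclear / cytoplasmic / whole-cell OD, the nuclear-to-
cytoplasmic (N:C) ratio, and cell-level H-scores.

Compartments (background / nucleus / cytoplasm) come from a per-pixel
random-forest classifier trained on labelled images; tumor cellular area is
the union of nucleus and cytoplasm.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian
from skimage.measure import label as cc_label
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)

LABEL_BACKGROUND, LABEL_NUCLEUS, LABEL_CYTOPLASM = 0, 1, 2

# Standard brightfield stain colours (unit vectors in OD space):
# hematoxylin and DAB per the classical orthonormal calibration.
_HEMATOXYLIN = np.array([0.650, 0.704, 0.286])
_DAB = np.array([0.269, 0.568, 0.778])


@dataclass(frozen=True)
class StainModel:
    """2-3 linearly independent unit-norm stain colour vectors in OD space."""

    names: tuple[str, ...]
    vectors: np.ndarray  # (k, 3)

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or not 2 <= v.shape[0] <= 3:
            raise ValueError("stain vectors must be a (k, 3) array with k in {2, 3}")
        if len(self.names) != v.shape[0]:
            raise ValueError("one name per stain vector required")
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms <= 0):
            raise ValueError("stain vectors must be nonzero")
        object.__setattr__(self, "vectors", v / norms[:, None])
        if np.linalg.matrix_rank(self.vectors, tol=1e-8) < v.shape[0]:
            raise ValueError("stain vectors are collinear")

    def stain_index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown stain {name!r}; have {self.names}") from None


def default_stain_model() -> StainModel:
    return StainModel(("hematoxylin", "dab"), np.vstack([_HEMATOXYLIN, _DAB]))


@dataclass
class IhcImage:
    """RGB brightfield image with a per-channel white reference I0."""

    pixels: np.ndarray  # (H, W, 3), float or int, in [0, I0]
    white_reference: np.ndarray | None = None  # (3,), estimated if None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be H x W x 3 with H, W >= 1")
        self.pixels = px
        if self.white_reference is not None:
            self.white_reference = np.asarray(self.white_reference, dtype=float).reshape(3)


@dataclass
class CompartmentMasks:
    """Label image over {background, nucleus, cytoplasm} plus tumor mask.

    Invariants: nucleus and cytoplasm are disjoint by construction of the
    label image; tumor_mask contains their union.
    """

    labels: np.ndarray  # (H, W) int in {0, 1, 2}
    tumor_mask: np.ndarray | None = None  # defaults to labels > 0

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("label image must be 2-D")
        if not np.isin(lab, [LABEL_BACKGROUND, LABEL_NUCLEUS, LABEL_CYTOPLASM]).all():
            raise ValueError("labels must be in {0, 1, 2}")
        self.labels = lab.astype(np.uint8)
        if self.tumor_mask is None:
            self.tumor_mask = self.labels > 0
        else:
            self.tumor_mask = np.asarray(self.tumor_mask, dtype=bool)
            if self.tumor_mask.shape != self.labels.shape:
                raise ValueError("tumor_mask shape mismatch")
            if ((self.labels > 0) & ~self.tumor_mask).any():
                raise ValueError("nucleus/cytoplasm must lie inside tumor_mask")

    @property
    def nucleus(self) -> np.ndarray:
        return self.labels == LABEL_NUCLEUS

    @property
    def cytoplasm(self) -> np.ndarray:
        return self.labels == LABEL_CYTOPLASM


@dataclass
class IhcReadout:
    """Continuous IHC readouts for one stain on one image."""

    stain: str
    od_nuclear: float | None = None
    od_cytoplasmic: float | None = None
    od_whole_cell: float | None = None
    nc_ratio: float | None = None
    nc_ratio_defined: bool = False
    h_score: float | None = None
    pct_bins: dict[str, float] | None = None
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# optical density and stain separation


def estimate_white_reference(pixels: np.ndarray, percentile: float = 99.0) -> np.ndarray:
    """Per-channel white point as a high percentile (robust to debris)."""
    return np.percentile(np.asarray(pixels, dtype=float).reshape(-1, 3), percentile, axis=0)


def rgb_to_od(image: IhcImage | np.ndarray, white_reference=None) -> np.ndarray:
    """Per-pixel, per-channel optical density, OD = -log10(I/I0) >= 0.

    Intensities are clamped to >= 1 count before the log; pixels brighter
    than I0 clamp to OD 0.
    """
    if isinstance(image, IhcImage):
        pixels = image.pixels
        if white_reference is None:
            white_reference = image.white_reference
    else:
        pixels = np.asarray(image, dtype=float)
    if white_reference is None:
        white_reference = estimate_white_reference(pixels)
    i0 = np.asarray(white_reference, dtype=float).reshape(3)
    if np.any(i0 <= 0):
        raise ValueError("white reference must be positive in every channel")
    intensity = np.clip(pixels, 1.0, None)
    od = -np.log10(intensity / i0)
    return np.clip(od, 0.0, None)


def od_to_rgb(od: np.ndarray, white_reference) -> np.ndarray:
    """Invert Beer-Lambert: I = I0 * 10**(-OD)."""
    i0 = np.asarray(white_reference, dtype=float).reshape(3)
    return i0 * np.power(10.0, -np.asarray(od, dtype=float))


def separate_stains(od_image: np.ndarray, model: StainModel | None = None) -> np.ndarray:
    """Least-squares unmixing of an OD image into per-stain concentrations.

    Returns an (H, W, k) array of non-negative concentrations (negative
    least-squares solutions are clipped to 0).
    """
    model = model or default_stain_model()
    od = np.asarray(od_image, dtype=float)
    flat = od.reshape(-1, 3)
    conc = flat @ np.linalg.pinv(model.vectors)
    return np.clip(conc, 0.0, None).reshape(od.shape[:2] + (len(model.names),))


def recompose_stains(concentrations: np.ndarray, model: StainModel | None = None) -> np.ndarray:
    """Forward model: concentrations (H, W, k) -> OD image (H, W, 3)."""
    model = model or default_stain_model()
    conc = np.asarray(concentrations, dtype=float)
    flat = conc.reshape(-1, conc.shape[-1]) @ model.vectors
    return flat.reshape(conc.shape[:-1] + (3,))


# ---------------------------------------------------------------------------
# pixel classification


@dataclass
class PixelClassifier:
    """Random-forest per-pixel compartment classifier plus its feature config."""

    forest: RandomForestClassifier
    stain_model: StainModel
    smoothing_sigma: float
    version: str = "1"

    def save(self, path: str | Path) -> None:
        path = Path(path)
        joblib.dump({"forest": self.forest, "stain_names": self.stain_model.names,
                     "stain_vectors": self.stain_model.vectors,
                     "smoothing_sigma": self.smoothing_sigma, "version": self.version}, path)
        sidecar = {
            "version": self.version,
            "stains": list(self.stain_model.names),
            "smoothing_sigma": self.smoothing_sigma,
            "n_estimators": self.forest.n_estimators,
            "classes": [int(c) for c in self.forest.classes_],
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PixelClassifier":
        blob = joblib.load(path)
        return cls(
            forest=blob["forest"],
            stain_model=StainModel(tuple(blob["stain_names"]), blob["stain_vectors"]),
            smoothing_sigma=blob["smoothing_sigma"],
            version=blob.get("version", "1"),
        )


def _pixel_features(image: IhcImage, model: StainModel, sigma: float) -> np.ndarray:
    od = rgb_to_od(image)
    conc = separate_stains(od, model)
    smooth = gaussian(od, sigma=sigma, channel_axis=-1)
    feats = np.concatenate([od, conc, smooth], axis=2)
    return feats.reshape(-1, feats.shape[2])


def train_pixel_classifier(
    images: list[IhcImage],
    masks: list[CompartmentMasks],
    seed: int,
    *,
    stain_model: StainModel | None = None,
    smoothing_sigma: float = 2.0,
    n_estimators: int = 50,
    max_pixels: int = 60_000,
) -> PixelClassifier:
    """Train the compartment classifier on labelled images.

    All three classes (background, nucleus, cytoplasm) must be present in
    the pooled labels; training pixels are subsampled to ``max_pixels``
    deterministically from ``seed``.
    """
    if not images:
        raise ValueError("need at least one labelled image")
    if len(images) != len(masks):
        raise ValueError("one mask per image required")
    model = stain_model or default_stain_model()
    x = np.vstack([_pixel_features(im, model, smoothing_sigma) for im in images])
    y = np.concatenate([m.labels.ravel() for m in masks])
    present = set(np.unique(y).tolist())
    required = {LABEL_BACKGROUND, LABEL_NUCLEUS, LABEL_CYTOPLASM}
    if not required <= present:
        raise ValueError(f"training labels missing classes: {sorted(required - present)}")
    rng = np.random.default_rng(seed)
    if x.shape[0] > max_pixels:
        idx = rng.choice(x.shape[0], size=max_pixels, replace=False)
        x, y = x[idx], y[idx]
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=int(seed) % (2**31), n_jobs=1,
        min_samples_leaf=2,
    )
    forest.fit(x, y)
    return PixelClassifier(forest, model, smoothing_sigma)


def segment_compartments(image: IhcImage, classifier: PixelClassifier) -> CompartmentMasks:
    """Predict a compartment label per pixel; tumor = nucleus + cytoplasm."""
    if not hasattr(classifier.forest, "classes_"):
        raise ValueError("classifier is not trained")
    feats = _pixel_features(image, classifier.stain_model, classifier.smoothing_sigma)
    labels = classifier.forest.predict(feats).reshape(image.pixels.shape[:2])
    return CompartmentMasks(labels.astype(np.uint8))


# ---------------------------------------------------------------------------
# readouts


def measure_compartment_od(
    stain_maps: np.ndarray,
    masks: CompartmentMasks,
    stain: str,
    model: StainModel | None = None,
) -> IhcReadout:
    """Mean stain OD per compartment plus the N:C ratio.

    ``stain_maps`` is the (H, W, k) concentration array from
    ``separate_stains``. Empty compartments yield absent means and an
    explicitly flagged, undefined N:C ratio.
    """
    model = model or default_stain_model()
    maps = np.asarray(stain_maps, dtype=float)
    if maps.shape[:2] != masks.labels.shape:
        raise ValueError("stain maps and masks have different shapes")
    conc = maps[..., model.stain_index(stain)]
    out = IhcReadout(stain=stain)
    nuc, cyt, tumor = masks.nucleus, masks.cytoplasm, masks.tumor_mask
    if nuc.any():
        out.od_nuclear = float(conc[nuc].mean())
    else:
        out.flags.append("empty_nucleus")
    if cyt.any():
        out.od_cytoplasmic = float(conc[cyt].mean())
    else:
        out.flags.append("empty_cytoplasm")
    if tumor.any():
        out.od_whole_cell = float(conc[tumor].mean())
    else:
        out.flags.append("empty_tumor_mask")
    if out.od_nuclear is not None and out.od_cytoplasmic not in (None, 0.0):
        out.nc_ratio = out.od_nuclear / out.od_cytoplasmic
        out.nc_ratio_defined = True
    else:
        out.flags.append("nc_ratio_undefined")
    return out


def cell_mean_intensities(
    stain_map: np.ndarray,
    masks: CompartmentMasks,
    *,
    compartment: str = "nucleus",
) -> np.ndarray:
    """Per-cell mean stain concentration.

    Cells are connected components of the nucleus mask. ``compartment`` is
    ``"nucleus"`` (nuclear markers such as MYC or Ki-67) or ``"cell"``
    (nucleus plus its surrounding cytoplasm, assigned by proximity).
    """
    nuclei = cc_label(masks.nucleus, connectivity=2)
    n_cells = int(nuclei.max())
    if n_cells == 0:
        raise ValueError("no nuclei found")
    conc = np.asarray(stain_map, dtype=float)
    if compartment == "nucleus":
        assign = nuclei
    elif compartment == "cell":
        # propagate nearest-nucleus identity across the tumor area
        _, (ri, ci) = ndi.distance_transform_edt(nuclei == 0, return_indices=True)
        assign = nuclei[ri, ci]
        assign = np.where(masks.tumor_mask, assign, 0)
    else:
        raise ValueError("compartment must be 'nucleus' or 'cell'")
    means = ndi.mean(conc, labels=assign, index=np.arange(1, n_cells + 1))
    return np.asarray(means, dtype=float)


DEFAULT_HSCORE_THRESHOLDS = (0.15, 0.40, 0.80)


def h_score(
    cell_intensities,
    thresholds=DEFAULT_HSCORE_THRESHOLDS,
    *,
    stain: str = "dab",
) -> IhcReadout:
    """H-score from per-cell staining intensities.

    Cells bin by mean stain OD: <= t1 -> 0, (t1, t2] -> 1+, (t2, t3] -> 2+,
    > t3 -> 3+; H = 1*pct(1+) + 2*pct(2+) + 3*pct(3+), range [0, 300].
    """
    vals = np.asarray(cell_intensities, dtype=float)
    if vals.size == 0:
        raise ValueError("empty cell list")
    t = np.asarray(thresholds, dtype=float)
    if t.size != 3 or not (t[0] < t[1] < t[2]):
        raise ValueError("need 3 strictly ascending thresholds")
    bins = np.digitize(vals, t, right=True)  # 0..3 per the bin rule above
    pct = {f"{i}": 100.0 * float((bins == i).sum()) / vals.size for i in range(4)}
    score = 1.0 * pct["1"] + 2.0 * pct["2"] + 3.0 * pct["3"]
    return IhcReadout(
        stain=stain,
        h_score=float(score),
        pct_bins={"0": pct["0"], "1+": pct["1"], "2+": pct["2"], "3+": pct["3"]},
    )
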