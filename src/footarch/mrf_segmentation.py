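"""Dense contact-region labeling by MRF energy minimization.

The sparse contact points are densified into a connected region by segmenting
the foot-point image into three classes — contact, non-contact, background —
with a 4-connected pairwise MRF. The energy of a labeling c is

    E(c) = sum_i  w_psi * psi(c_i, x_i) + w_lam * lam(c_i, d_i)
                 + w_rho * rho(c_i, theta_i)
         + sum_(i,j) I(c_i != c_j) * exp(-beta * ||x_i - x_j||^2)

with per-class negative log densities of color x (3-component RGB GMM), plane
distance d (scalar Gaussian) and normal-to-plate angle theta (scalar
Gaussian), and a contrast-sensitive Potts smoothness term. The class models
are trained per frame from the contact-point detection itself. Inference is
alpha-expansion graph cuts (ICM is available as a fallback backend).

Default term weights are (2.9, 9.3, 1.8) for color, distance and angle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from ._graphcut import binary_mincut
from .contact_points import (
    ContactPointSet,
    NormalField,
    Plane,
    estimate_normals,
    signed_distance,
)
from .io_camera import FootPointCloud
from scipy.ndimage import binary_dilation

__all__ = [
    "CONTACT",
    "NON_CONTACT",
    "BACKGROUND",
    "DEFAULT_WEIGHTS",
    "UnaryFeatures",
    "PotentialParams",
    "MRFModel",
    "ContactLabeling",
    "build_features",
    "sample_training_points",
    "fit_potentials",
    "unary_energy",
    "compute_unaries",
    "smoothness_energy",
    "total_energy",
    "infer_labels",
    "detect_contact_region",
]

CONTACT, NON_CONTACT, BACKGROUND = 0, 1, 2
N_CLASSES = 3
DEFAULT_WEIGHTS = (2.9, 9.3, 1.8)
MIN_PROB = 1e-12  # density floor before taking -log
MIN_STD = 1e-3


@dataclass
class UnaryFeatures:
    """Per-pixel features feeding the unary potentials."""

    colors: np.ndarray  # (H, W, 3) RGB in [0, 255]
    d: np.ndarray  # (H, W) signed plane distance, mm
    theta: np.ndarray  # (H, W) angle between point and plate normals, deg
    valid: np.ndarray  # (H, W) bool


@dataclass
class ScalarGaussian:
    mean: float
    std: float

    def __post_init__(self) -> None:
        self.std = max(float(self.std), MIN_STD)

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        z = (x - self.mean) / self.std
        return -0.5 * z * z - np.log(self.std * np.sqrt(2.0 * np.pi))


@dataclass
class PotentialParams:
    """Per-class density models for the three unary terms."""

    color_models: list  # GaussianMixture per class
    distance_models: list  # ScalarGaussian per class
    angle_models: list  # ScalarGaussian per class


@dataclass
class MRFModel:
    params: PotentialParams
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS
    beta: float = 1.0
    smoothness_scale: float = 1.0  # 0 decouples the pixels (diagnostic hook)

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass
class ContactLabeling:
    labels: np.ndarray  # (H, W) uint8 in {CONTACT, NON_CONTACT, BACKGROUND}
    energy: float


def build_features(
    cloud: FootPointCloud,
    plane: Plane,
    normal_field: NormalField | None = None,
) -> UnaryFeatures:
    """Assemble colors, plane distances and normal angles for every pixel.

    Invalid pixels carry the background archetype (black, d = 0, theta = 180)
    so that the feature grids are fully defined.
    """
    if normal_field is None:
        normal_field = estimate_normals(cloud)
    h, w = cloud.valid.shape
    d = np.zeros((h, w))
    d[cloud.valid] = signed_distance(plane, cloud.points[cloud.valid])
    cosang = normal_field.normals @ plane.normal
    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    theta[~normal_field.valid] = 180.0
    # pixels with a valid point but no normal estimate: neutral angle of the
    # plate itself so the angle term does not dominate there
    theta[cloud.valid & ~normal_field.valid] = 0.0
    colors = np.where(cloud.valid[..., None], cloud.colors, 0.0)
    return UnaryFeatures(colors=colors, d=d, theta=theta, valid=cloud.valid)


def sample_training_points(
    cloud: FootPointCloud,
    contacts: ContactPointSet,
    features: UnaryFeatures,
    n_per_class: int = 500,
    seed: int = 0,
    dilation_radius: int = 5,
    bg_sigma: tuple[float, float, float] = (2.0, 0.1, 1.0),
) -> dict[int, dict[str, np.ndarray]]:
    """Draw per-class training samples for the potential models.

    Contact samples come from the sparse contact points; non-contact samples
    from foot points outside the dilated contact mask (so sparsity of the
    contact detection does not leak contact pixels into the non-contact
    class); background samples are the fixed archetype (black color, zero
    distance, 180 deg angle) with small Gaussian perturbations.
    """
    if not contacts.mask.any():
        raise ValueError("contact point set is empty")
    rng = np.random.default_rng(seed)
    r = dilation_radius
    yy, xx = np.mgrid[-r: r + 1, -r: r + 1]
    disk = (xx * xx + yy * yy) <= r * r
    dilated = binary_dilation(contacts.mask, structure=disk)
    noncontact = cloud.valid & ~dilated
    if not noncontact.any():
        warnings.warn(
            "no non-contact candidates after dilation; "
            "falling back to the undilated complement",
            stacklevel=2,
        )
        noncontact = cloud.valid & ~contacts.mask

    def _draw(mask: np.ndarray) -> dict[str, np.ndarray]:
        idx = np.flatnonzero(mask.ravel())
        pick = rng.choice(idx, size=min(n_per_class, idx.size),
                          replace=idx.size < n_per_class)
        v, u = np.unravel_index(pick, mask.shape)
        return {
            "color": features.colors[v, u],
            "distance": features.d[v, u],
            "angle": features.theta[v, u],
        }

    s_col, s_d, s_a = bg_sigma
    n = n_per_class

    def _archetype() -> dict[str, np.ndarray]:
        return {
            "color": np.clip(rng.normal(0.0, s_col, size=(n, 3)), 0, 255),
            "distance": rng.normal(0.0, s_d, size=n),
            "angle": np.clip(rng.normal(180.0, s_a, size=n), 0, 180),
        }

    if noncontact.any():
        nc_samples = _draw(noncontact)
    else:
        # fully-contact frame: there is no evidence for a non-contact class,
        # so it gets the background archetype and stays inert
        warnings.warn("every foot point is a contact point; the non-contact "
                      "class is trained on the background archetype",
                      stacklevel=2)
        nc_samples = _archetype()
    return {
        CONTACT: _draw(contacts.mask),
        NON_CONTACT: nc_samples,
        BACKGROUND: _archetype(),
    }


def fit_potentials(
    samples: dict[int, dict[str, np.ndarray]], seed: int = 0
) -> PotentialParams:
    """Fit per-class RGB GMMs (3 components, EM) and scalar Gaussians."""
    color_models, dist_models, angle_models = [], [], []
    for cls in (CONTACT, NON_CONTACT, BACKGROUND):
        s = samples[cls]
        if len(s["color"]) < 10:
            raise ValueError(f"need >= 10 samples for class {cls}")
        gmm = GaussianMixture(
            n_components=3,
            covariance_type="full",
            reg_covar=1e-3,
            tol=1e-4,
            max_iter=200,
            init_params="kmeans",
            random_state=seed,
        )
        gmm.fit(np.asarray(s["color"], dtype=float))
        color_models.append(gmm)
        dist_models.append(
            ScalarGaussian(float(np.mean(s["distance"])),
                           float(np.std(s["distance"], ddof=1))))
        angle_models.append(
            ScalarGaussian(float(np.mean(s["angle"])),
                           float(np.std(s["angle"], ddof=1))))
    return PotentialParams(color_models, dist_models, angle_models)


def _neglog(logp: np.ndarray) -> np.ndarray:
    return -np.maximum(logp, np.log(MIN_PROB))


def unary_energy(
    label: int,
    color: np.ndarray,
    d: float | np.ndarray,
    theta: float | np.ndarray,
    model: MRFModel,
) -> np.ndarray:
    """w_psi*psi + w_lam*lam + w_rho*rho for one class at given features."""
    wpsi, wlam, wrho = model.weights
    p = model.params
    color = np.atleast_2d(np.asarray(color, dtype=float))
    psi = _neglog(p.color_models[label].score_samples(color))
    lam = _neglog(p.distance_models[label].logpdf(d))
    rho = _neglog(p.angle_models[label].logpdf(theta))
    out = wpsi * psi + wlam * lam + wrho * rho
    return out[0] if out.size == 1 else out


def compute_unaries(features: UnaryFeatures, model: MRFModel) -> np.ndarray:
    """(H, W, 3) unary energies for every pixel and class."""
    h, w = features.valid.shape
    flat_c = features.colors.reshape(-1, 3)
    flat_d = features.d.ravel()
    flat_t = features.theta.ravel()
    wpsi, wlam, wrho = model.weights
    p = model.params
    U = np.zeros((h * w, N_CLASSES))
    for cls in range(N_CLASSES):
        psi = _neglog(p.color_models[cls].score_samples(flat_c))
        lam = _neglog(p.distance_models[cls].logpdf(flat_d))
        rho = _neglog(p.angle_models[cls].logpdf(flat_t))
        U[:, cls] = wpsi * psi + wlam * lam + wrho * rho
    return U.reshape(h, w, N_CLASSES)


def smoothness_energy(ci, cj, xi, xj, beta: float) -> float:
    """Contrast-sensitive Potts: I(ci != cj) exp(-beta ||xi - xj||^2)."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if ci == cj:
        return 0.0
    diff = np.asarray(xi, dtype=float) - np.asarray(xj, dtype=float)
    return float(np.exp(-beta * float(diff @ diff)))


def default_beta(features: UnaryFeatures) -> float:
    """Contrast normalization: beta = 1 / (2 <||xi - xj||^2>) on grid edges."""
    c = features.colors
    d2 = []
    d2.append(((c[:, 1:] - c[:, :-1]) ** 2).sum(-1).ravel())
    d2.append(((c[1:, :] - c[:-1, :]) ** 2).sum(-1).ravel())
    mean = float(np.concatenate(d2).mean())
    return 1.0 / (2.0 * mean) if mean > 0 else 1.0


def _edge_weights(features: UnaryFeatures, model: MRFModel):
    """4-connected edges (flat indices) and their Potts coefficients."""
    h, w = features.valid.shape
    idx = np.arange(h * w).reshape(h, w)
    c = features.colors
    ei = [idx[:, :-1].ravel(), idx[:-1, :].ravel()]
    ej = [idx[:, 1:].ravel(), idx[1:, :].ravel()]
    d2 = [((c[:, 1:] - c[:, :-1]) ** 2).sum(-1).ravel(),
          ((c[1:, :] - c[:-1, :]) ** 2).sum(-1).ravel()]
    ei = np.concatenate(ei)
    ej = np.concatenate(ej)
    wts = model.smoothness_scale * np.exp(
        -model.beta * np.concatenate(d2))
    return ei, ej, wts


def total_energy(
    labeling: ContactLabeling | np.ndarray,
    features: UnaryFeatures,
    model: MRFModel,
    unaries: np.ndarray | None = None,
) -> float:
    """Evaluate the full MRF energy of a labeling.

    Unary terms are summed over valid pixels (invalid pixels are clamped to
    background and carry no unary cost); the Potts term is summed over each
    4-connected edge once.
    """
    labels = labeling.labels if isinstance(labeling, ContactLabeling) \
        else np.asarray(labeling)
    if unaries is None:
        unaries = compute_unaries(features, model)
    v = features.valid
    h, w = v.shape
    flat = labels.reshape(h * w)
    e_unary = float(
        unaries.reshape(-1, N_CLASSES)[np.arange(h * w), flat][v.ravel()].sum()
    )
    ei, ej, wts = _edge_weights(features, model)
    e_pair = float((wts * (flat[ei] != flat[ej])).sum())
    return e_unary + e_pair


def _expansion_move(
    labels_flat: np.ndarray,
    alpha: int,
    unaries_flat: np.ndarray,
    valid_flat: np.ndarray,
    ei: np.ndarray,
    ej: np.ndarray,
    wts: np.ndarray,
) -> np.ndarray:
    """One alpha-expansion: binary cut between keeping labels and taking alpha.

    Invalid pixels stay clamped to background; edges touching them fold into
    the variable pixel's unary terms.
    """
    var = np.flatnonzero(valid_flat)
    pos = np.full(labels_flat.size, -1, dtype=np.int64)
    pos[var] = np.arange(var.size)
    L = labels_flat
    theta0 = unaries_flat[var, L[var]].astype(float).copy()
    theta1 = unaries_flat[var, alpha].astype(float).copy()

    vi, vj = valid_flat[ei], valid_flat[ej]
    both = vi & vj
    # edges with one clamped (background) endpoint fold into the unary
    mask_i = vi & ~vj
    np.add.at(theta0, pos[ei[mask_i]],
              wts[mask_i] * (L[ei[mask_i]] != BACKGROUND))
    np.add.at(theta1, pos[ei[mask_i]],
              wts[mask_i] * (alpha != BACKGROUND))
    mask_j = vj & ~vi
    np.add.at(theta0, pos[ej[mask_j]],
              wts[mask_j] * (L[ej[mask_j]] != BACKGROUND))
    np.add.at(theta1, pos[ej[mask_j]],
              wts[mask_j] * (alpha != BACKGROUND))

    bi, bj, bw = ei[both], ej[both], wts[both]
    e00 = bw * (L[bi] != L[bj])
    e01 = bw * (L[bi] != alpha)
    e10 = bw * (L[bj] != alpha)
    e11 = np.zeros_like(bw)
    x = binary_mincut(theta0, theta1, pos[bi], pos[bj], e00, e01, e10, e11)
    out = labels_flat.copy()
    out[var[x == 1]] = alpha
    return out


def infer_labels(
    features: UnaryFeatures,
    model: MRFModel,
    backend: str = "graphcut",
    max_sweeps: int = 10,
) -> ContactLabeling:
    """Approximately minimize the MRF energy over the three labels.

    Initialization is the per-pixel unary argmin (invalid pixels are fixed to
    background). The graph-cut backend runs alpha-expansion sweeps until no
    move lowers the energy; each accepted move is verified to decrease the
    exact (floating-point) energy, so the returned labeling never has higher
    energy than the initialization.
    """
    unaries = compute_unaries(features, model)
    h, w = features.valid.shape
    flatU = unaries.reshape(-1, N_CLASSES)
    valid_flat = features.valid.ravel()
    labels = np.argmin(flatU, axis=1).astype(np.uint8)
    labels[~valid_flat] = BACKGROUND
    ei, ej, wts = _edge_weights(features, model)

    def energy(lb: np.ndarray) -> float:
        e_u = float(flatU[np.arange(lb.size), lb][valid_flat].sum())
        return e_u + float((wts * (lb[ei] != lb[ej])).sum())

    e_cur = energy(labels)
    if backend == "graphcut":
        for _ in range(max_sweeps):
            improved = False
            for alpha in (CONTACT, NON_CONTACT, BACKGROUND):
                prop = _expansion_move(labels, alpha, flatU, valid_flat,
                                       ei, ej, wts)
                e_new = energy(prop)
                if e_new < e_cur - 1e-9:
                    assert e_new <= e_cur, "expansion increased the energy"
                    labels, e_cur = prop, e_new
                    improved = True
            if not improved:
                break
    elif backend == "icm":
        labels, e_cur = _icm(labels, flatU, valid_flat, ei, ej, wts,
                             (h, w), energy, max_sweeps=5 * max_sweeps)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return ContactLabeling(labels=labels.reshape(h, w), energy=e_cur)


def _icm(labels, flatU, valid_flat, ei, ej, wts, shape, energy_fn,
         max_sweeps: int = 50):
    """Checkerboard iterated conditional modes (exact coordinate descent)."""
    h, w = shape
    vv, uu = np.divmod(np.arange(h * w), w)
    parity = ((vv + uu) % 2).astype(bool)
    e_cur = energy_fn(labels)
    for _ in range(max_sweeps):
        changed = False
        for phase in (False, True):
            local = flatU.copy()
            for lab in range(N_CLASSES):
                pair = np.zeros(h * w)
                np.add.at(pair, ei, wts * (labels[ej] != lab))
                np.add.at(pair, ej, wts * (labels[ei] != lab))
                local[:, lab] += pair
            upd = valid_flat & (parity == phase)
            new = labels.copy()
            new[upd] = np.argmin(local[upd], axis=1).astype(np.uint8)
            if np.any(new != labels):
                e_new = energy_fn(new)
                assert e_new <= e_cur + 1e-9, "ICM increased the energy"
                labels, e_cur = new, min(e_new, e_cur)
                changed = True
        if not changed:
            break
    return labels, e_cur


def detect_contact_region(
    cloud: FootPointCloud,
    plane: Plane,
    contacts: ContactPointSet,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    seed: int = 0,
    n_per_class: int = 500,
    dilation_radius: int = 5,
    beta: float | None = None,
    backend: str = "graphcut",
    normal_field: NormalField | None = None,
) -> ContactLabeling:
    """End-to-end MRF contact-region detection for one frame."""
    features = build_features(cloud, plane, normal_field)
    samples = sample_training_points(
        cloud, contacts, features,
        n_per_class=n_per_class, seed=seed, dilation_radius=dilation_radius,
    )
    params = fit_potentials(samples, seed=seed)
    model = MRFModel(
        params=params,
        weights=tuple(weights),
        beta=default_beta(features) if beta is None else beta,
    )
    return infer_labels(features, model, backend=backend)
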