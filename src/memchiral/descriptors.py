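"""Eleven geometric and chirality descriptors of a 3-D point cloud.

All descriptors treat atoms as unweighted points (the compactness measure is
the unweighted root-mean-square distance to the centroid, not a mass-weighted
radius of gyration). Spreads use population (ddof=0) statistics throughout.

Descriptor summary
------------------
rg       root-mean-square atom-centroid distance (A); compactness
sasa     solvent-accessible surface area (A^2); filled by surface_metrics
gai      geometric asymmetry index: sigma/mu of centroid distances
cm       chiral moment: norm of the mean cross product of consecutive
         centroid-relative position vectors (A^2); atom-order dependent
soc      spatial-orientation chirality: |N_left - N_right| / N about the
         first principal axis, in [0, 1]
hci      helical chirality index: population variance of distances from the
         principal axis (A^2)
aci      axial chirality index: mean absolute circular deviation of azimuths
         about the principal axis (radians, [0, pi])
cai      circular asymmetry index: |sum of azimuth signs| / N, in [0, 1]
me       morphometric ellipticity: ratio of largest to smallest principal
         standard deviation (>= 1)
fd       box-counting fractal dimension
rdf_het  coefficient of variation of the radial distribution g(r) over
         occupied bins (scalar heterogeneity reduction of the RDF)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Column order frozen for report/TSV output.
DESCRIPTOR_NAMES = (
    "rg", "sasa", "gai", "cm", "soc", "hci", "aci", "cai", "me", "fd",
    "rdf_het",
)

_AXIS_TOL = 1e-9  # relative threshold below which an atom sits "on" the axis


class DegenerateGeometryError(ValueError):
    """Raised when a descriptor is undefined for the given cloud."""


class PointCloud:
    """An ordered set of N 3-D coordinates with its unweighted centroid."""

    def __init__(self, coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise ValueError("coords must be an (N>=1, 3) array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords must be finite")
        self.coords = coords

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @property
    def centered(self) -> np.ndarray:
        return self.coords - self.centroid

    def centroid_distances(self) -> np.ndarray:
        return np.linalg.norm(self.centered, axis=1)


@dataclass
class PrincipalFrame:
    """Orthonormal principal axes (descending variance) and their SDs.

    Sign convention: each of e1, e2 is flipped so its largest-magnitude
    component is positive, then e3 = e1 x e2 (right-handed). SDs are square
    roots of population-covariance eigenvalues.
    """

    axes: np.ndarray  # (3, 3), rows e1, e2, e3
    sds: np.ndarray   # (3,), s1 >= s2 >= s3

    @property
    def e1(self) -> np.ndarray:
        return self.axes[0]

    @property
    def e2(self) -> np.ndarray:
        return self.axes[1]

    @property
    def e3(self) -> np.ndarray:
        return self.axes[2]


@dataclass
class RadialProfile:
    """Histogram of atom-centroid distances normalised to a g(r).

    rho is the mean density N / (4/3 pi r_max^3); g(r_k) = n_k /
    (4 pi r_k^2 dr rho) with r_k the bin centre. Counts conserve N.
    """

    r_max: float
    n_bins: int
    delta_r: float
    bin_centers: np.ndarray
    counts: np.ndarray
    rho: float
    g: np.ndarray


@dataclass
class BoxCountSeries:
    """Dyadic box-counting series and the fitted log-log slope."""

    scales: np.ndarray   # strictly decreasing voxel sizes (A)
    counts: np.ndarray   # occupied voxel counts
    slope: float


@dataclass
class DescriptorVector:
    """The eleven descriptors of one structure, with typed missing values.

    A descriptor that is undefined for the input (e.g. ellipticity of a
    planar cloud) is stored as None with the reason in ``missing``.
    """

    structure_id: str
    values: dict[str, float | None] = field(default_factory=dict)
    missing: dict[str, str] = field(default_factory=dict)

    def as_row(self) -> dict[str, float | None]:
        row: dict[str, float | None] = {"structure_id": self.structure_id}
        for name in DESCRIPTOR_NAMES:
            row[name] = self.values.get(name)
        return row


# ---------------------------------------------------------------------------
# scalar descriptors


def radius_of_gyration(cloud: PointCloud) -> float:
    """Root-mean-square distance of atoms from the unweighted centroid (A)."""
    d = cloud.centroid_distances()
    return float(np.sqrt(np.mean(d ** 2)))


def geometric_asymmetry_index(cloud: PointCloud) -> float:
    """Coefficient of variation (population sigma / mu) of centroid distances."""
    if cloud.n < 2:
        raise DegenerateGeometryError("GAI needs at least 2 atoms")
    d = cloud.centroid_distances()
    mu = float(d.mean())
    if mu <= 0.0:
        raise DegenerateGeometryError("degenerate cloud: all atoms at centroid")
    return float(d.std(ddof=0) / mu)


def chiral_moment(cloud: PointCloud) -> float:
    """Norm of the mean cross product of consecutive centroid-relative vectors.

    Consecutive means file order, non-cyclic: the mean runs over the N-1
    adjacent pairs. Translation invariant; the pre-norm vector co-rotates
    with the cloud, so the norm is rotation invariant. Note the norm is also
    reflection invariant, so this index does not separate mirror images.
    """
    if cloud.n < 2:
        raise DegenerateGeometryError("insufficient atoms for chiral moment")
    return float(np.linalg.norm(chiral_moment_vector(cloud)))


def chiral_moment_vector(cloud: PointCloud) -> np.ndarray:
    """Mean cross-product vector behind :func:`chiral_moment` (frame-dependent)."""
    if cloud.n < 2:
        raise DegenerateGeometryError("insufficient atoms for chiral moment")
    c = cloud.centered
    crosses = np.cross(c[:-1], c[1:])
    return crosses.mean(axis=0)


def principal_frame(cloud: PointCloud) -> PrincipalFrame:
    """Principal axes and SDs from the population covariance of the cloud."""
    if cloud.n < 2:
        raise DegenerateGeometryError("principal frame needs >= 2 atoms")
    c = cloud.centered
    cov = (c.T @ c) / cloud.n
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    axes = evecs[:, order].T
    if evals[0] <= 0.0:
        raise DegenerateGeometryError("degenerate cloud: zero extent")
    for k in (0, 1):
        j = int(np.argmax(np.abs(axes[k])))
        if axes[k][j] < 0:
            axes[k] = -axes[k]
    axes[2] = np.cross(axes[0], axes[1])
    return PrincipalFrame(axes=axes, sds=np.sqrt(evals))


def spatial_orientation_chirality(cloud: PointCloud,
                                  frame: PrincipalFrame) -> float:
    """Normalised left/right imbalance about the first principal axis.

    Atoms projecting to exactly zero count in the denominator but on neither
    side, keeping the index in [0, 1] and independent of the axis sign.
    """
    p = cloud.centered @ frame.e1
    n_right = int(np.sum(p > 0))
    n_left = int(np.sum(p < 0))
    return abs(n_left - n_right) / cloud.n


def helical_chirality_index(cloud: PointCloud, frame: PrincipalFrame) -> float:
    """Population variance of atom distances from the first principal axis (A^2)."""
    r = _radial_distances(cloud, frame)
    return float(r.var(ddof=0))


def _radial_distances(cloud: PointCloud, frame: PrincipalFrame) -> np.ndarray:
    c = cloud.centered
    axial = c @ frame.e1
    return np.linalg.norm(c - np.outer(axial, frame.e1), axis=1)


def azimuths(cloud: PointCloud, frame: PrincipalFrame) -> np.ndarray:
    """Signed azimuths in (-pi, pi] of off-axis atoms about e1.

    The azimuth is measured in the (e2, e3) plane from e2 toward e3; atoms on
    the e1 axis (undefined azimuth) are excluded. Raises if every atom is
    on-axis.
    """
    c = cloud.centered
    u = c @ frame.e2
    v = c @ frame.e3
    r = np.hypot(u, v)
    scale = max(float(np.abs(c).max()), 1.0)
    off = r > _AXIS_TOL * scale
    if not np.any(off):
        raise DegenerateGeometryError("degenerate azimuths: all atoms on axis")
    theta = np.arctan2(v[off], u[off])
    # arctan2 returns [-pi, pi]; fold -pi onto +pi for the (-pi, pi] contract
    theta[theta == -np.pi] = np.pi
    return theta


def circular_mean(theta: np.ndarray) -> float:
    """Circular mean angle of a sample, in (-pi, pi]."""
    m = float(np.arctan2(np.mean(np.sin(theta)), np.mean(np.cos(theta))))
    return np.pi if m == -np.pi else m


def _wrap_angle(x: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    w = np.mod(x + np.pi, 2 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)


def axial_chirality_index(cloud: PointCloud, frame: PrincipalFrame) -> float:
    """Mean absolute circular deviation of azimuths from their circular mean.

    Result in [0, pi] radians; invariant to rotations about the principal
    axis and to rigid motions of the cloud.
    """
    theta = azimuths(cloud, frame)
    if theta.size < 2:
        raise DegenerateGeometryError("ACI needs >= 2 off-axis atoms")
    ref = circular_mean(theta)
    return float(np.mean(np.abs(_wrap_angle(theta - ref))))


def circular_asymmetry_index(cloud: PointCloud, frame: PrincipalFrame) -> float:
    """Normalised imbalance of azimuth signs, |sum sign(theta)| / N, in [0, 1].

    N is the off-axis atom count; azimuths of exactly 0 or pi have sign 0.
    The absolute value makes the index independent of the arbitrary PCA axis
    signs.
    """
    theta = azimuths(cloud, frame)
    signs = np.sign(theta)
    signs[theta == np.pi] = 0.0
    return float(abs(signs.sum()) / theta.size)


def morphometric_ellipticity(cloud: PointCloud, frame: PrincipalFrame) -> float:
    """Ratio s1/s3 of largest to smallest principal SD; >= 1 by construction."""
    if frame.sds[2] <= 0.0:
        raise DegenerateGeometryError("degenerate: zero minor axis")
    return float(frame.sds[0] / frame.sds[2])


def fractal_dimension(cloud: PointCloud, min_scales: int = 3
                      ) -> tuple[float, BoxCountSeries]:
    """Box-counting dimension over a dyadic scale ladder.

    Voxel grids are anchored at the min-corner of the bounding box with sizes
    L/2^k (L the largest box-edge extent); scales where the occupied count is
    1 (everything in one box) or N (every atom isolated) carry no slope
    information and are dropped. The dimension is the OLS slope of
    log N(eps) against log(1/eps).
    """
    if cloud.n < 10:
        raise DegenerateGeometryError("fractal dimension needs >= 10 atoms")
    lo = cloud.coords.min(axis=0)
    extent = cloud.coords.max(axis=0) - lo
    L = float(extent.max())
    if L <= 0.0:
        raise DegenerateGeometryError("degenerate cloud: zero extent")
    scales, counts = [], []
    max_k = min(int(np.ceil(np.log2(cloud.n))) + 2, 24)
    for k in range(1, max_k + 1):
        eps = L / 2 ** k
        idx = np.floor((cloud.coords - lo) / eps).astype(np.int64)
        idx = np.minimum(idx, 2 ** k - 1)  # points on the max face
        n_occ = len(np.unique(idx, axis=0))
        if 1 < n_occ < cloud.n:
            scales.append(eps)
            counts.append(n_occ)
        if n_occ >= cloud.n:
            break
    if len(scales) < min_scales:
        raise DegenerateGeometryError(
            f"insufficient scale range: {len(scales)} usable scales "
            f"(need {min_scales})")
    scales_arr = np.array(scales)
    counts_arr = np.array(counts)
    slope = float(np.polyfit(np.log(1.0 / scales_arr),
                             np.log(counts_arr), 1)[0])
    return slope, BoxCountSeries(scales_arr, counts_arr, slope)


def radial_distribution(cloud: PointCloud, n_bins: int = 50) -> RadialProfile:
    """Shell-normalised radial density of atoms about the centroid.

    g(r_k) = n_k / (4 pi r_k^2 dr rho) with rho = 3N / (4 pi r_max^3) and
    r_k the bin centre; the final bin is right-closed so the atom at exactly
    r_max is counted and sum(n_k) = N.
    """
    if cloud.n < 2:
        raise DegenerateGeometryError("RDF needs >= 2 atoms")
    d = cloud.centroid_distances()
    r_max = float(d.max())
    if r_max <= 0.0:
        raise DegenerateGeometryError("degenerate cloud: zero radial extent")
    counts, edges = np.histogram(d, bins=n_bins, range=(0.0, r_max))
    delta_r = r_max / n_bins
    centers = 0.5 * (edges[:-1] + edges[1:])
    rho = 3.0 * cloud.n / (4.0 * np.pi * r_max ** 3)
    g = counts / (4.0 * np.pi * centers ** 2 * delta_r * rho)
    return RadialProfile(r_max=r_max, n_bins=n_bins, delta_r=delta_r,
                         bin_centers=centers, counts=counts, rho=rho, g=g)


def rdf_heterogeneity(profile: RadialProfile) -> float:
    """Population CV of g(r) over occupied bins; 0 for a uniform density."""
    occ = profile.counts > 0
    if int(occ.sum()) < 2:
        raise DegenerateGeometryError("insufficient profile: < 2 occupied bins")
    g = profile.g[occ]
    return float(g.std(ddof=0) / g.mean())


# ---------------------------------------------------------------------------
# assembly


def compute_all(model, spec=None, sasa_cfg=None,
                rdf_bins: int = 50, fd_min_scales: int = 3) -> DescriptorVector:
    """All eleven descriptors for one classified structure.

    Descriptors undefined for the input are recorded as missing with a
    reason instead of aborting the whole vector. SASA is delegated to
    :mod:`memchiral.surface_metrics`.
    """
    from .structure_io import SelectionSpec, select_atoms
    from .surface_metrics import RadiiTable, sasa as _sasa

    if spec is None:
        spec = SelectionSpec(mode="all")
    cloud = select_atoms(model, spec)
    vec = DescriptorVector(structure_id=model.id)

    def attempt(name, fn, *args):
        try:
            vec.values[name] = fn(*args)
        except DegenerateGeometryError as exc:
            vec.values[name] = None
            vec.missing[name] = str(exc)

    attempt("rg", radius_of_gyration, cloud)
    attempt("gai", geometric_asymmetry_index, cloud)
    attempt("cm", chiral_moment, cloud)

    frame = None
    try:
        frame = principal_frame(cloud)
    except DegenerateGeometryError as exc:
        for name in ("soc", "hci", "aci", "cai", "me"):
            vec.values[name] = None
            vec.missing[name] = str(exc)
    if frame is not None:
        attempt("soc", spatial_orientation_chirality, cloud, frame)
        attempt("hci", helical_chirality_index, cloud, frame)
        attempt("aci", axial_chirality_index, cloud, frame)
        attempt("cai", circular_asymmetry_index, cloud, frame)
        attempt("me", morphometric_ellipticity, cloud, frame)

    try:
        fd, _ = fractal_dimension(cloud, min_scales=fd_min_scales)
        vec.values["fd"] = fd
    except DegenerateGeometryError as exc:
        vec.values["fd"] = None
        vec.missing["fd"] = str(exc)

    try:
        profile = radial_distribution(cloud, n_bins=rdf_bins)
        vec.values["rdf_het"] = rdf_heterogeneity(profile)
    except DegenerateGeometryError as exc:
        vec.values["rdf_het"] = None
        vec.missing["rdf_het"] = str(exc)

    sasa_cfg = sasa_cfg or {}
    radii = sasa_cfg.get("radii", RadiiTable())
    n_points = sasa_cfg.get("n_sphere_points", 960)
    try:
        total, _ = _sasa(model, spec, radii=radii, n_sphere_points=n_points)
        vec.values["sasa"] = total
    except ValueError as exc:
        vec.values["sasa"] = None
        vec.missing["sasa"] = str(exc)
    return vec


# ---------------------------------------------------------------------------
# estimator interface


class DescriptorExtractor:
    """Transformer mapping structures to the 11-descriptor feature matrix.

    Follows the scikit-learn transformer protocol: ``fit`` is stateless
    (returns self), ``transform`` takes a list of classified
    :class:`~memchiral.structure_io.StructureModel` objects and returns a
    pandas DataFrame with one row per structure, indexed by structure id,
    columns in :data:`DESCRIPTOR_NAMES` order. Missing (degenerate)
    descriptors appear as NaN; reasons are collected in ``missing_``.

    Parameters
    ----------
    selection : str
        Atom selection mode (all/protein/lipid/backbone).
    n_sphere_points : int
        Shrake-Rupley sphere-point count for SASA.
    probe_radius : float
        Solvent probe radius in Angstroms.
    rdf_bins, fd_min_scales : int
        RDF histogram bins; minimum usable box-counting scales.
    """

    def __init__(self, selection: str = "all", n_sphere_points: int = 960,
                 probe_radius: float = 1.4, rdf_bins: int = 50,
                 fd_min_scales: int = 3):
        self.selection = selection
        self.n_sphere_points = n_sphere_points
        self.probe_radius = probe_radius
        self.rdf_bins = rdf_bins
        self.fd_min_scales = fd_min_scales

    def get_params(self, deep: bool = True) -> dict:
        return {
            "selection": self.selection,
            "n_sphere_points": self.n_sphere_points,
            "probe_radius": self.probe_radius,
            "rdf_bins": self.rdf_bins,
            "fd_min_scales": self.fd_min_scales,
        }

    def set_params(self, **params) -> "DescriptorExtractor":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X=None, y=None) -> "DescriptorExtractor":
        self.missing_: dict[str, dict[str, str]] = {}
        return self

    def transform(self, X):
        import pandas as pd

        from .structure_io import SelectionSpec
        from .surface_metrics import RadiiTable

        if not hasattr(self, "missing_"):
            self.fit()
        spec = SelectionSpec(mode=self.selection)
        sasa_cfg = {"radii": RadiiTable(probe=self.probe_radius),
                    "n_sphere_points": self.n_sphere_points}
        rows = []
        for model in X:
            vec = compute_all(model, spec, sasa_cfg,
                              rdf_bins=self.rdf_bins,
                              fd_min_scales=self.fd_min_scales)
            if vec.missing:
                self.missing_[model.id] = dict(vec.missing)
            rows.append(vec.as_row())
        df = pd.DataFrame(rows).set_index("structure_id")
        return df.astype(float)

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)
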