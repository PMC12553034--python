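"""Parameter containers and their fixed, named vectorization.

Every quantity of the canonical-microcircuit (CMC) model is carried on the
log scale relative to a conventional default, following the usual neural-mass
convention: the effective value is ``default * exp(theta)``, so ``theta = 0``
is the prior mean and additive effects on ``theta`` are multiplicative
modulations of the physical quantity.

The :class:`ParameterLayout` assigns a stable name and position to every
scalar parameter of a given network, independent of which model variant is
being fitted; model variants differ only in which entries receive positive
prior variance.  A single layout shared across a model space is what makes
analytic Bayesian model reduction across that space possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "POPULATIONS",
    "INTRINSIC_GAIN_LABELS",
    "SP_GAIN_INDEX",
    "CMCParameters",
    "ParameterLayout",
    "GaussianDensity",
    "PriorDensity",
]

#: Cell populations of one cortical column, in state order.
POPULATIONS = ("ss", "sp", "ii", "dp")  # spiny stellate, superficial pyramidal,
#                                         inhibitory interneuron, deep pyramidal

#: The ten signed intrinsic connections of the canonical microcircuit,
#: labelled target<-source.  ``sp<-sp`` is the superficial-pyramidal
#: self-inhibition ("gain modulation") parameter singled out by the analyses.
INTRINSIC_GAIN_LABELS = (
    "ss<-ss",
    "ss<-ii",
    "ss<-sp",
    "sp<-ss",
    "sp<-sp",
    "ii<-ss",
    "ii<-dp",
    "ii<-ii",
    "dp<-ii",
    "dp<-dp",
)

#: Index of the superficial-pyramidal self-gain within INTRINSIC_GAIN_LABELS.
SP_GAIN_INDEX = INTRINSIC_GAIN_LABELS.index("sp<-sp")


@dataclass
class CMCParameters:
    """Log-scale parameters of one subject's CMC network model.

    Arrays are dense over the layout's support; entries that a model variant
    forbids are simply pinned by a zero-variance prior.

    Attributes
    ----------
    log_T : (R, 4) array
        Log scaling of the population rate constants (order ``POPULATIONS``).
    log_G : (R, 10) array
        Log scaling of the intrinsic gains (order ``INTRINSIC_GAIN_LABELS``).
    log_A_fwd, log_A_bwd : (E_f,), (E_b,) arrays
        Log scaling of extrinsic forward / backward connection weights, one
        entry per edge of the layout's connection support.
    B_fwd, B_bwd : (E_f,), (E_b,) arrays
        Repetition-modulation coefficients on the extrinsic connections
        (applied through the exponential basis column).
    B_sp : (R,) array
        Repetition-modulation coefficients on the superficial-pyramidal gain
        (applied through the phasic basis column; only meaningful for
        exponential-plus-phasic models).
    log_C_aud, log_C_exp : arrays
        Input gains for the auditory and expectancy drives (one entry per
        region in the respective input set of the layout).
    log_D : float
        Log scaling of the extrinsic conduction delay.
    log_S : float
        Log scaling of the sigmoid slope.
    log_L : (R,) array
        Per-region lead-field (source amplitude) gains.
    """

    log_T: np.ndarray
    log_G: np.ndarray
    log_A_fwd: np.ndarray
    log_A_bwd: np.ndarray
    B_fwd: np.ndarray
    B_bwd: np.ndarray
    B_sp: np.ndarray
    log_C_aud: np.ndarray
    log_C_exp: np.ndarray
    log_D: float
    log_S: float
    log_L: np.ndarray

    def copy(self) -> "CMCParameters":
        return CMCParameters(
            self.log_T.copy(), self.log_G.copy(),
            self.log_A_fwd.copy(), self.log_A_bwd.copy(),
            self.B_fwd.copy(), self.B_bwd.copy(), self.B_sp.copy(),
            self.log_C_aud.copy(), self.log_C_exp.copy(),
            float(self.log_D), float(self.log_S), self.log_L.copy(),
        )


class ParameterLayout:
    """Stable name <-> index mapping for the parameters of one region set.

    Parameters
    ----------
    region_names : sequence of str
    fwd_edges, bwd_edges : sequence of (src, dst) index pairs
        The connection support (union over the model space).
    aud_regions, exp_regions : sequence of int
        Regions that can receive auditory / expectancy input.
    """

    def __init__(self, region_names, fwd_edges, bwd_edges, aud_regions, exp_regions):
        self.region_names = tuple(region_names)
        self.fwd_edges = [tuple(e) for e in fwd_edges]
        self.bwd_edges = [tuple(e) for e in bwd_edges]
        self.aud_regions = list(aud_regions)
        self.exp_regions = list(exp_regions)
        self.n_regions = len(self.region_names)

        names: list[str] = []
        classes: list[str] = []
        rn = self.region_names
        for r in range(self.n_regions):
            for p in POPULATIONS:
                names.append(f"T[{rn[r]}].{p}")
                classes.append("T")
        for r in range(self.n_regions):
            for g in INTRINSIC_GAIN_LABELS:
                names.append(f"G[{rn[r]}].{g}")
                classes.append("G")
        for (s, d) in self.fwd_edges:
            names.append(f"A_fwd[{rn[s]}->{rn[d]}]")
            classes.append("A")
        for (s, d) in self.bwd_edges:
            names.append(f"A_bwd[{rn[s]}->{rn[d]}]")
            classes.append("A")
        for (s, d) in self.fwd_edges:
            names.append(f"B_fwd[{rn[s]}->{rn[d]}]")
            classes.append("B")
        for (s, d) in self.bwd_edges:
            names.append(f"B_bwd[{rn[s]}->{rn[d]}]")
            classes.append("B")
        for r in range(self.n_regions):
            names.append(f"B_sp[{rn[r]}]")
            classes.append("B")
        for r in self.aud_regions:
            names.append(f"C_aud[{rn[r]}]")
            classes.append("C")
        for r in self.exp_regions:
            names.append(f"C_exp[{rn[r]}]")
            classes.append("C")
        names.append("D")
        classes.append("D")
        names.append("S")
        classes.append("S")
        for r in range(self.n_regions):
            names.append(f"L[{rn[r]}]")
            classes.append("L")

        self.names: tuple[str, ...] = tuple(names)
        self.classes: tuple[str, ...] = tuple(classes)
        self.index = {n: i for i, n in enumerate(names)}
        self.size = len(names)

    # -- conversions ------------------------------------------------------

    def zeros(self) -> CMCParameters:
        """A parameter set at the prior mean (all log scalings zero)."""
        R = self.n_regions
        return CMCParameters(
            log_T=np.zeros((R, 4)),
            log_G=np.zeros((R, 10)),
            log_A_fwd=np.zeros(len(self.fwd_edges)),
            log_A_bwd=np.zeros(len(self.bwd_edges)),
            B_fwd=np.zeros(len(self.fwd_edges)),
            B_bwd=np.zeros(len(self.bwd_edges)),
            B_sp=np.zeros(R),
            log_C_aud=np.zeros(len(self.aud_regions)),
            log_C_exp=np.zeros(len(self.exp_regions)),
            log_D=0.0,
            log_S=0.0,
            log_L=np.zeros(R),
        )

    def to_vector(self, p: CMCParameters) -> np.ndarray:
        return np.concatenate([
            np.asarray(p.log_T, float).ravel(),
            np.asarray(p.log_G, float).ravel(),
            np.asarray(p.log_A_fwd, float).ravel(),
            np.asarray(p.log_A_bwd, float).ravel(),
            np.asarray(p.B_fwd, float).ravel(),
            np.asarray(p.B_bwd, float).ravel(),
            np.asarray(p.B_sp, float).ravel(),
            np.asarray(p.log_C_aud, float).ravel(),
            np.asarray(p.log_C_exp, float).ravel(),
            [float(p.log_D), float(p.log_S)],
            np.asarray(p.log_L, float).ravel(),
        ])

    def from_vector(self, v: np.ndarray) -> CMCParameters:
        v = np.asarray(v, float)
        if v.shape != (self.size,):
            raise ValueError(f"expected vector of length {self.size}, got {v.shape}")
        R = self.n_regions
        Ef, Eb = len(self.fwd_edges), len(self.bwd_edges)
        o = 0

        def take(n, shape=None):
            nonlocal o
            out = v[o:o + n]
            o += n
            return out.reshape(shape) if shape else out

        return CMCParameters(
            log_T=take(4 * R, (R, 4)),
            log_G=take(10 * R, (R, 10)),
            log_A_fwd=take(Ef),
            log_A_bwd=take(Eb),
            B_fwd=take(Ef),
            B_bwd=take(Eb),
            B_sp=take(R),
            log_C_aud=take(len(self.aud_regions)),
            log_C_exp=take(len(self.exp_regions)),
            log_D=float(take(1)[0]),
            log_S=float(take(1)[0]),
            log_L=take(R),
        )

    def names_of_class(self, cls: str) -> list[str]:
        return [n for n, c in zip(self.names, self.classes) if c == cls]

    def sp_gain_names(self) -> list[str]:
        """Names of the superficial-pyramidal self-gain parameters."""
        return [f"G[{r}].sp<-sp" for r in self.region_names]


@dataclass
class GaussianDensity:
    """A multivariate Gaussian over a named parameter (sub)vector."""

    mean: np.ndarray
    cov: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        self.mean = np.asarray(self.mean, float)
        self.cov = np.asarray(self.cov, float)
        n = self.mean.shape[0]
        if self.cov.shape != (n, n):
            raise ValueError("covariance shape does not match mean")
        if len(self.labels) != n:
            raise ValueError("labels do not match dimension")
        self.labels = tuple(self.labels)
        asym = np.max(np.abs(self.cov - self.cov.T)) if n else 0.0
        if asym > 1e-8 * (1.0 + np.max(np.abs(self.cov))):
            raise ValueError("covariance is not symmetric")
        self.cov = 0.5 * (self.cov + self.cov.T)

    @property
    def size(self) -> int:
        return self.mean.shape[0]

    def marginal(self, labels) -> "GaussianDensity":
        idx = [self.labels.index(l) for l in labels]
        return GaussianDensity(self.mean[idx], self.cov[np.ix_(idx, idx)], tuple(labels))


@dataclass
class PriorDensity:
    """Diagonal Gaussian prior over a full parameter layout.

    ``variance`` entries equal to zero pin the parameter to its prior mean;
    the free parameter set of a model is exactly the positive-variance set.
    """

    mean: np.ndarray
    variance: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        self.mean = np.asarray(self.mean, float)
        self.variance = np.asarray(self.variance, float)
        if np.any(self.variance < 0):
            raise ValueError("negative prior variance")
        self.labels = tuple(self.labels)

    @property
    def free_mask(self) -> np.ndarray:
        return self.variance > 0

    @property
    def free_labels(self) -> tuple[str, ...]:
        return tuple(np.asarray(self.labels)[self.free_mask])

    def free_density(self) -> GaussianDensity:
        m = self.free_mask
        return GaussianDensity(self.mean[m], np.diag(self.variance[m]), self.free_labels)

    def copy(self) -> "PriorDensity":
        return PriorDensity(self.mean.copy(), self.variance.copy(), self.labels)
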