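"""One-dimensional discrete stationary wavelet transform (undecimated / à trous).

The transform convolves the signal with the analysis filter pair at each
level, upsampling the filters by ``2**(level-1)`` instead of downsampling the
signal, so every coefficient array keeps the input length and the transform
commutes with circular shifts.  Boundaries are handled by circular (periodic)
extension; signals whose length is not divisible by ``2**levels`` are
right-padded by edge replication and truncated again after reconstruction.

The basis registry covers eight families / 56 bases: Daubechies db2-db8,
Symlets sym2-sym8, Coiflets coif2-coif5, biorthogonal splines (15), reverse
biorthogonal (15), Haar, discrete Meyer, and Fejer-Korovkin fk4-fk22.
Daubechies through Haar filters come from the standard PyWavelets tables.
The discrete Meyer FIR table is only approximately orthogonal as published,
so the registry stores its projection onto the orthonormal QMF manifold
(nearest filter, distance ~1e-3); the Fejer-Korovkin family is constructed
in-package from the Fejer-Korovkin kernel (see ``_fk_filter``).  Every
registered basis satisfies the perfect-reconstruction identity to 1e-10,
which is asserted at registry build time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pywt

__all__ = [
    "WaveletBasis",
    "SWTDecomposition",
    "registry",
    "lookup",
    "swt_decompose",
    "swt_reconstruct",
    "denoise",
    "denoise_matrix",
]

ORTHOGONAL_FAMILIES = {
    "daubechies",
    "symlets",
    "coiflets",
    "haar",
    "dmeyer",
    "Fejer-Korovkin",
}
BIORTHOGONAL_FAMILIES = {"biorSplines", "reverseBior"}

#: (family, member basis names) in registry order
FAMILY_MEMBERS = (
    ("daubechies", tuple(f"db{i}" for i in range(2, 9))),
    ("symlets", tuple(f"sym{i}" for i in range(2, 9))),
    ("coiflets", tuple(f"coif{i}" for i in range(2, 6))),
    (
        "biorSplines",
        tuple(
            f"bior{i}"
            for i in (
                "1.1", "1.3", "1.5", "2.2", "2.4", "2.6", "2.8",
                "3.1", "3.3", "3.5", "3.7", "3.9", "4.4", "5.5", "6.8",
            )
        ),
    ),
    (
        "reverseBior",
        tuple(
            f"rbio{i}"
            for i in (
                "1.1", "1.3", "1.5", "2.2", "2.4", "2.6", "2.8",
                "3.1", "3.3", "3.5", "3.7", "3.9", "4.4", "5.5", "6.8",
            )
        ),
    ),
    ("haar", ("haar",)),
    ("dmeyer", ("dmeyer",)),
    ("Fejer-Korovkin", tuple(f"fk{i}" for i in (4, 6, 8, 14, 18, 22))),
)


class UnknownBasisError(KeyError):
    """Requested basis name is not in the 56-member registry."""


@dataclass(frozen=True)
class WaveletBasis:
    """A registered wavelet basis: family, canonical name and its filter bank.

    ``lo_d``/``hi_d`` are the decomposition (analysis) low/high-pass filters,
    ``lo_r``/``hi_r`` the reconstruction (synthesis) pair.  For orthogonal
    families the synthesis filters are the time-reversed analysis filters and
    the quadrature-mirror relation links low and high pass; biorthogonal
    families carry genuinely dual filter pairs.
    """

    family: str
    name: str
    lo_d: np.ndarray = field(repr=False)
    hi_d: np.ndarray = field(repr=False)
    lo_r: np.ndarray = field(repr=False)
    hi_r: np.ndarray = field(repr=False)

    @property
    def filter_length(self) -> int:
        return max(len(self.lo_d), len(self.lo_r))

    def reconstruction_delay(self) -> int:
        """Group delay of the composite analysis+synthesis filter.

        ``0.5*(lo_r * lo_d + hi_r * hi_d)`` (full convolutions) is a Kronecker
        delta for a perfect-reconstruction bank; its index is the circular
        shift undone after each synthesis step.
        """
        comp = 0.5 * (
            np.convolve(self.lo_r, self.lo_d) + np.convolve(self.hi_r, self.hi_d)
        )
        k0 = int(np.argmax(np.abs(comp)))
        resid = np.abs(comp).sum() - abs(comp[k0])
        if resid > 1e-8 or abs(comp[k0] - 1.0) > 1e-8:
            raise ValueError(
                f"filter bank of {self.name!r} is not perfect-reconstruction "
                f"(delta residual {resid:.2e})"
            )
        return k0


@dataclass
class SWTDecomposition:
    """Per-level same-length coefficient arrays of a stationary transform.

    ``approx[l]`` / ``detail[l]`` hold the level-``l+1`` low/high-frequency
    channels; every array has the padded working length, and
    ``original_length`` records the input length restored on reconstruction.
    """

    basis: WaveletBasis
    levels: int
    approx: list[np.ndarray]
    detail: list[np.ndarray]
    original_length: int

    def __post_init__(self) -> None:
        if len(self.approx) != self.levels or len(self.detail) != self.levels:
            raise ValueError("approx/detail must hold one array per level")
        n = len(self.approx[0])
        for arr in (*self.approx, *self.detail):
            if len(arr) != n:
                raise ValueError("all coefficient arrays must share one length")
        if n < self.original_length:
            raise ValueError("working length shorter than original signal")


# ---------------------------------------------------------------------------
# Filter construction for the two bases absent from (or defective in) the
# installed filter tables.
# ---------------------------------------------------------------------------


def _spectral_factor(autocorr_odd: np.ndarray, length: int) -> np.ndarray:
    """Orthonormal filter from its autocorrelation's odd-lag coefficients.

    ``autocorr_odd[j]`` is the lag-``(2j+1)`` autocorrelation (even lags are
    zero by the QMF half-band property, lag 0 is one).  Factorizes
    ``W(z) = sum_k r_k z^k`` by root pairing, keeping one root of each
    ``(z, 1/z)`` pair and every second unit-circle root.
    """
    r = np.zeros(length)
    r[0] = 1.0
    r[1::2] = autocorr_odd
    roots = np.roots(np.concatenate([r[::-1], r[1:]]))
    inside = roots[np.abs(roots) < 1 - 1e-7]
    on_circle = roots[np.abs(np.abs(roots) - 1) <= 1e-7]
    on_circle = on_circle[np.argsort(np.angle(on_circle))][::2]
    h = np.real(np.poly(np.concatenate([1.0 / inside, on_circle])))
    h /= np.sqrt(h @ h)
    if h.sum() < 0:
        h = -h
    if abs(h[0]) < abs(h[-1]):  # orient with the dominant taps leading
        h = h[::-1]
    return h


def _fk_filter(length: int) -> np.ndarray:
    """Fejer-Korovkin orthonormal scaling filter of the given even length.

    The squared frequency response is the ideal half-band indicator smoothed
    by the Fejer-Korovkin kernel of order ``length-1`` (which preserves the
    QMF partition of unity exactly and is the kernel with maximal first
    Fourier coefficient among nonnegative kernels, hence the family's sharp
    frequency localization), plus the smallest L1 correction on the odd
    harmonics that restores one vanishing moment while keeping the response
    nonnegative.  The filter is the oriented spectral factor.
    """
    from scipy.optimize import linprog

    n = length - 1
    m_grid = 1 << 16
    t = (np.arange(m_grid) + 0.5) * 2 * np.pi / m_grid - np.pi
    alpha = np.pi / (n + 2)
    kernel = (2 * np.sin(alpha) ** 2 / (n + 2)) * (
        np.cos((n + 2) * t / 2) / (np.cos(alpha) - np.cos(t))
    ) ** 2
    kappa = np.real(np.fft.fft(np.fft.ifftshift(kernel)) / m_grid)
    ks = np.arange(1, n + 1, 2)
    b0 = 4 * kappa[ks] * np.sin(ks * np.pi / 2) / (ks * np.pi)
    deficit = 1.0 - b0.sum()

    # minimal |c|_1 with  W0 + sum_j c_j cos(j w) >= eps*(1+cos w),  sum c = deficit
    n_c = len(ks)
    w = np.linspace(0, np.pi, 16384)
    cos_jw = np.cos(np.outer(w, ks))
    w0 = 1 + cos_jw @ b0
    margin = 1e-8 * (1 + np.cos(w))
    a_ub = np.vstack(
        [
            np.hstack([-cos_jw, np.zeros((len(w), n_c))]),
            np.hstack([np.eye(n_c), -np.eye(n_c)]),
            np.hstack([-np.eye(n_c), -np.eye(n_c)]),
        ]
    )
    b_ub = np.concatenate([w0 - margin, np.zeros(2 * n_c)])
    res = linprog(
        np.concatenate([np.zeros(n_c), np.ones(n_c)]),
        A_ub=a_ub,
        b_ub=b_ub,
        A_eq=np.hstack([np.ones((1, n_c)), np.zeros((1, n_c))]),
        b_eq=[deficit],
        bounds=[(None, None)] * n_c + [(0, None)] * n_c,
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"fk{length}: vanishing-moment correction infeasible")
    return _spectral_factor((b0 + res.x[:n_c]) / 2, length)


def _orthogonalized_dmey() -> np.ndarray:
    """Nearest exactly-orthonormal filter to the published discrete Meyer table.

    The 62-tap FIR Meyer approximation violates the orthonormality
    constraints at the 1e-3 level, which would leak into every
    reconstruction; this projects it onto the QMF manifold (unit norm, zero
    even-lag autocorrelation, sum sqrt(2)) by SLSQP, moving each tap by
    ~1e-3 at most.
    """
    from scipy.optimize import minimize

    h0 = np.array(pywt.Wavelet("dmey").dec_lo)[::-1]  # convolution orientation
    n = len(h0)

    def constraints(h):
        lags = [h @ h - 1.0]
        lags += [h[:-s] @ h[s:] for s in range(2, n, 2)]
        lags.append(h.sum() - np.sqrt(2))
        return np.array(lags)

    res = minimize(
        lambda h: ((h - h0) ** 2).sum(),
        h0,
        jac=lambda h: 2 * (h - h0),
        constraints={"type": "eq", "fun": constraints},
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-18},
    )
    h = res.x
    if np.abs(constraints(h)).max() > 1e-10:
        raise RuntimeError("discrete Meyer orthogonalization did not converge")
    return h


def _orthogonal_bank(lo_d: np.ndarray) -> tuple[np.ndarray, ...]:
    """Full filter bank of an orthonormal scaling filter (convolution form)."""
    lo_d = np.asarray(lo_d, float)
    n = len(lo_d)
    hi_d = ((-1.0) ** (np.arange(n) + 1)) * lo_d[::-1]  # pywt sign convention
    return lo_d, hi_d, lo_d[::-1], hi_d[::-1]


@lru_cache(maxsize=1)
def _build_registry() -> dict[str, WaveletBasis]:
    reg: dict[str, WaveletBasis] = {}
    for family, members in FAMILY_MEMBERS:
        for name in members:
            if family == "Fejer-Korovkin":
                lo_d, hi_d, lo_r, hi_r = _orthogonal_bank(_fk_filter(int(name[2:])))
            elif family == "dmeyer":
                lo_d, hi_d, lo_r, hi_r = _orthogonal_bank(_orthogonalized_dmey())
            else:
                w = pywt.Wavelet(name)
                lo_d, hi_d, lo_r, hi_r = (
                    np.array(w.dec_lo),
                    np.array(w.dec_hi),
                    np.array(w.rec_lo),
                    np.array(w.rec_hi),
                )
            basis = WaveletBasis(family, name, lo_d, hi_d, lo_r, hi_r)
            basis.reconstruction_delay()  # assert PR at build time
            reg[name] = basis
    return reg


def registry() -> list[WaveletBasis]:
    """All 56 registered bases, in family order."""
    return list(_build_registry().values())


def lookup(name: str) -> WaveletBasis:
    """Basis by canonical name (``"bior1.5"``, ``"fk14"``, ``"dmeyer"``...)."""
    try:
        return _build_registry()[name]
    except KeyError:
        raise UnknownBasisError(
            f"unknown wavelet basis {name!r}; see wavprog.dswt.registry()"
        ) from None


# ---------------------------------------------------------------------------
# Transform
# ---------------------------------------------------------------------------


def _circular_conv(x: np.ndarray, filt: np.ndarray, level: int) -> np.ndarray:
    """Circular convolution with the filter upsampled by ``2**(level-1)``."""
    n = len(x)
    step = 2 ** (level - 1)
    fp = np.zeros(n)
    idx = (np.arange(len(filt)) * step) % n
    np.add.at(fp, idx, filt)
    return np.real(np.fft.ifft(np.fft.fft(x) * np.fft.fft(fp)))


def _padded_length(n: int, levels: int) -> int:
    block = 2**levels
    return ((n + block - 1) // block) * block


def max_levels(n: int) -> int:
    """Deepest decomposition for which a length-``n`` signal stays non-trivial."""
    return max(int(np.floor(np.log2(n))), 0) if n > 0 else 0


def swt_decompose(
    signal: np.ndarray, basis: WaveletBasis, levels: int = 2
) -> SWTDecomposition:
    """Stationary decomposition: recursively split the approximation branch.

    Each level splits the current low-frequency channel into new
    approximation and detail channels with the upsampled analysis filters;
    no downsampling, so all channels keep the (padded) signal length.
    """
    x = np.asarray(signal, float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    n = len(x)
    if n < 2:
        raise ValueError("signal must have at least 2 samples")
    feasible = max_levels(n)
    if levels > feasible:
        raise ValueError(
            f"levels={levels} too deep for signal of length {n}; "
            f"maximum feasible depth is {feasible}"
        )
    n_pad = _padded_length(n, levels)
    if n_pad != n:
        x = np.concatenate([x, np.full(n_pad - n, x[-1])])
    approx, detail = [], []
    a = x
    for lvl in range(1, levels + 1):
        detail.append(_circular_conv(a, basis.hi_d, lvl))
        a = _circular_conv(a, basis.lo_d, lvl)
        approx.append(a)
    return SWTDecomposition(basis, levels, approx, detail, n)


def swt_reconstruct(dec: SWTDecomposition) -> np.ndarray:
    """Inverse à-trous synthesis; exact to numerical precision.

    Each step merges approximation and detail through the upsampled synthesis
    filters, halves, and undoes the composite filter delay by a circular
    shift.
    """
    basis = dec.basis
    k0 = basis.reconstruction_delay()
    a = dec.approx[-1]
    for lvl in range(dec.levels, 0, -1):
        d = dec.detail[lvl - 1]
        if len(d) != len(a):
            raise ValueError("level/length mismatch in decomposition")
        y = 0.5 * (
            _circular_conv(a, basis.lo_r, lvl) + _circular_conv(d, basis.hi_r, lvl)
        )
        a = np.roll(y, -k0 * 2 ** (lvl - 1))
    return a[: dec.original_length]


def denoise(signal: np.ndarray, basis: WaveletBasis, levels: int = 2) -> np.ndarray:
    """Keep the low-frequency content: zero every detail channel, resynthesize.

    The result lives in the original signal space (same length, aligned with
    the input positions), i.e. the low-pass projection of the signal rather
    than raw approximation coefficients.
    """
    dec = swt_decompose(signal, basis, levels)
    for d in dec.detail:
        d[:] = 0.0
    return swt_reconstruct(dec)


def denoise_matrix(values, basis: WaveletBasis, levels: int = 2):
    """Denoise each sample's gene-profile vector (column) independently.

    ``values`` is a gene-by-sample DataFrame or 2-D array; gene order defines
    the 1-D signal. Returns the same container type with ids preserved.
    """
    import pandas as pd

    is_frame = isinstance(values, pd.DataFrame)
    mat = values.to_numpy(dtype=float) if is_frame else np.asarray(values, float)
    if mat.ndim != 2:
        raise ValueError("expected a gene-by-sample matrix")
    out = np.empty_like(mat)
    for j in range(mat.shape[1]):
        out[:, j] = denoise(mat[:, j], basis, levels)
    if is_frame:
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out
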