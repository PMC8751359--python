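"""Closed-form repression functions and ODE right-hand sides.

Six model families are covered:

* the three-phosphoform KaiC cycle with KaiA sequestration (``rhs_core``),
* its transcription-coupled extensions with S-inhibited (``TTFL``) or
  constitutive (``PTR``) transcription (``rhs_ttfl``),
* the Kim-Forger activator/repressor titration chain,
* the phospholock chain, in which the repressor complex is phosphorylated
  after binding the activator and only dissociates once phosphorylated,
* the phospholock chain with additional activator phosphorylation
  (the *Neurospora*-type variant).

All repression functions are algebraically the same quadratic free-activator
expression with different effective constants; see
``docs/repression_function.md`` for the quasi-steady-state derivation of the
effective-constant mapping used by :func:`effective_constants`.

Units: hours for time, arbitrary concentration units for abundances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CoreKaiParams",
    "TTFLParams",
    "KimForgerParams",
    "PhospholockParams",
    "NeurosporaParams",
    "StoichCondition",
    "free_kaiA",
    "kim_forger_f",
    "phospholock_f",
    "neurospora_f",
    "effective_constants",
    "rhs_core",
    "rhs_ttfl",
    "rhs_phospholock",
]


class DomainError(ValueError):
    """A model function was evaluated outside its mathematical domain."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise DomainError(f"{name} must be > 0, got {value!r}")


def _require_nonnegative(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise DomainError(f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class CoreKaiParams:
    """Rates and totals for the three-phosphoform sequestration oscillator."""

    k1: float
    k2: float
    k3: float
    k4: float
    Kd: float
    A_T: float
    C_T: float

    def __post_init__(self) -> None:
        _require_positive(k1=self.k1, k2=self.k2, k3=self.k3, k4=self.k4,
                          A_T=self.A_T, C_T=self.C_T)
        _require_nonnegative(Kd=self.Kd)

    def to_vector(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.k4, self.Kd,
                         self.A_T, self.C_T])


@dataclass(frozen=True)
class TTFLParams:
    """Five-state transcription-coupled KaiC model.

    ``mode`` selects the transcription term: ``"ttfl"`` uses the fold-change
    Hill repression by S (fold factor 100, Hill exponent 4, both structural
    constants), ``"ptr"`` a constitutive source.
    """

    k1: float
    k2: float
    k3: float
    k4: float
    Kd: float
    A_T: float
    V_trsp: float
    V_m: float
    K_s: float
    K_0: float
    V_d: float
    mode: str = "ttfl"

    hill_exponent: int = field(default=4, init=False)
    fold_factor: float = field(default=100.0, init=False)

    def __post_init__(self) -> None:
        _require_positive(k1=self.k1, k2=self.k2, k3=self.k3, k4=self.k4,
                          A_T=self.A_T, V_trsp=self.V_trsp, V_m=self.V_m,
                          K_s=self.K_s, K_0=self.K_0, V_d=self.V_d)
        _require_nonnegative(Kd=self.Kd)
        if self.mode not in ("ttfl", "ptr"):
            raise ValueError(f"mode must be 'ttfl' or 'ptr', got {self.mode!r}")

    def to_vector(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.k4, self.Kd,
                         self.A_T, self.V_trsp, self.V_m, self.K_s, self.K_0,
                         self.V_d, 1.0 if self.mode == "ttfl" else 0.0])

    def as_mode(self, mode: str) -> "TTFLParams":
        return replace(self, mode=mode)


@dataclass(frozen=True)
class KimForgerParams:
    """Simple activator/repressor titration chain (free-activator fraction)."""

    alpha1: float
    alpha2: float
    alpha3: float
    beta1: float
    beta2: float
    beta3: float
    A: float
    Kd: float

    def __post_init__(self) -> None:
        _require_positive(alpha1=self.alpha1, alpha2=self.alpha2,
                          alpha3=self.alpha3, beta1=self.beta1,
                          beta2=self.beta2, beta3=self.beta3, A=self.A)
        _require_nonnegative(Kd=self.Kd)


@dataclass(frozen=True)
class PhospholockParams:
    """Micro-rates of the phospholock repression chain.

    The binding scheme is A + R <-> AR (k1f/k1r), AR <-> ARp (k2f/k2r) and
    ARp -> A + ... (k3, dissociation of the phosphorylated complex).  Derived
    quantities ``Kd = k1r/k1f`` and ``k2 = k2f/k2r`` are recomputed on
    access, never stored.
    """

    alpha1: float
    alpha2: float
    alpha3: float
    beta1: float
    beta2: float
    beta3: float
    A_T: float
    k1f: float
    k1r: float
    k2f: float
    k2r: float
    k3: float

    def __post_init__(self) -> None:
        _require_positive(alpha1=self.alpha1, alpha2=self.alpha2,
                          alpha3=self.alpha3, beta1=self.beta1,
                          beta2=self.beta2, beta3=self.beta3, A_T=self.A_T)
        _require_nonnegative(k1f=self.k1f, k1r=self.k1r, k2f=self.k2f,
                            k2r=self.k2r, k3=self.k3)

    @property
    def Kd(self) -> float:
        return self.k1r / self.k1f

    @property
    def k2(self) -> float:
        return self.k2f / self.k2r

    @property
    def k4(self) -> float:
        return 0.0


@dataclass(frozen=True)
class NeurosporaParams(PhospholockParams):
    """Phospholock chain with activator phosphorylation A <-> Ap (k4f/k4r)."""

    k4f: float = 0.0
    k4r: float = 1.0

    def __post_init__(self) -> None:
        super().__post_init__()
        _require_nonnegative(k4f=self.k4f)
        if self.k4f > 0 and not self.k4r > 0:
            raise DomainError("k4r must be > 0 when k4f > 0")

    @property
    def k4(self) -> float:
        if self.k4f == 0.0:
            return 0.0
        return self.k4f / self.k4r


@dataclass(frozen=True)
class StoichCondition:
    """Total-abundance criterion C_T > (1 + r_const) * A_T + epsilon."""

    r_const: float = 2.0
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        _require_nonnegative(r_const=self.r_const, epsilon=self.epsilon)

    def holds(self, C_T, A_T):
        return np.asarray(C_T) > (1.0 + self.r_const) * np.asarray(A_T) + self.epsilon


# ---------------------------------------------------------------------------
# repression functions
# ---------------------------------------------------------------------------


def free_kaiA(S, A_T, Kd):
    """Free activator remaining when a sequestrant at concentration S
    titrates a total pool A_T with dissociation constant Kd.

    Positive root of ``A**2 + (S - A_T + Kd) A - Kd A_T = 0``; evaluated in a
    cancellation-safe form.  Continuous, non-increasing in S, in [0, A_T].
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise DomainError("S must be >= 0")
    if not A_T > 0:
        raise DomainError("A_T must be > 0")
    if Kd < 0:
        raise DomainError("Kd must be >= 0")
    q = A_T - S - Kd
    root = np.sqrt(q * q + 4.0 * Kd * A_T)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            q >= 0,
            0.5 * (q + root),
            np.where(root - q > 0, 2.0 * Kd * A_T / (root - q), 0.0),
        )
    return out if out.ndim else float(out)


def kim_forger_f(P, A, Kd):
    """Free-activator *fraction* for repressor P, total activator A."""
    if not A > 0:
        raise DomainError("A must be > 0")
    return free_kaiA(P, A, Kd) / A


def effective_constants(p: PhospholockParams):
    """Effective constants of the closed-form repression function.

    Quasi-steady-state analysis of the explicit binding scheme (see
    ``docs/repression_function.md``) gives

        K1 = k1f (k2f + k2r + k3)
        K2 = k1r (k2r + k3) + k2f k3

    so that ``K2 / K1`` is the effective dissociation constant of the
    locked activator/repressor pair.  For the activator-phosphorylation
    variant, dissociation of the locked complex releases the activator in
    its phosphorylated (inactive) form and recycles the repressor, which
    adds the phosphorylated-activator pool to the repressor's titration
    weight:

        K3 = K1 + k1f k3 k2f / k4r        (K3 = K1 for the plain chain).

    Validated against the numerically solved equilibrium of the explicit
    mass-action subnetwork (test suite, < 1e-6 relative error).
    """
    denom = p.k2f + p.k2r + p.k3
    if denom <= 0 or p.k1f <= 0:
        raise DomainError(
            "effective constants require k1f > 0 and k2f + k2r + k3 > 0"
        )
    K1 = p.k1f * denom
    K2 = p.k1r * (p.k2r + p.k3) + p.k2f * p.k3
    if isinstance(p, NeurosporaParams):
        if p.k3 * p.k2f > 0:
            if not p.k4r > 0:
                raise DomainError(
                    "k4r must be > 0 when the lock dissociates (k3 k2f > 0)"
                )
            K3 = K1 + p.k1f * p.k3 * p.k2f / p.k4r
        else:
            K3 = K1
        return K1, K2, K3
    return K1, K2


def _repression_quadratic(R, A_T, K1, K2, K3, k4):
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise DomainError("R must be >= 0")
    if not (K1 > 0 and K3 > 0):
        raise DomainError("effective constants K1, K3 must be > 0")
    if K2 < 0 or k4 < 0:
        raise DomainError("K2 and k4 must be >= 0")
    c = K2 * (1.0 + k4)
    num = K1 * A_T - K3 * R - c
    s = K1 * A_T + K3 * R + c
    disc = np.maximum(s * s - 4.0 * K1 * K3 * A_T * R, 0.0)
    root = np.sqrt(disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            num >= 0,
            (num + root) / (2.0 * K1 * (1.0 + k4)),
            np.where(
                root - num > 0,
                (disc - num * num) / (root - num) / (2.0 * K1 * (1.0 + k4)),
                0.0,
            ),
        )
    return out if out.ndim else float(out)


def phospholock_f(R, p: PhospholockParams):
    """Free activator for the phospholock chain at total repressor R."""
    K1, K2 = effective_constants(p)[:2]
    return _repression_quadratic(R, p.A_T, K1, K2, K1, 0.0)


def neurospora_f(R, p: NeurosporaParams):
    """Free activator with additional activator phosphorylation.

    Reduces to :func:`phospholock_f` when k4 = 0 (and K3 = K1, which the
    effective-constant mapping guarantees); f(0) = A_T / (1 + k4).
    """
    K1, K2, K3 = effective_constants(p)
    return _repression_quadratic(R, p.A_T, K1, K2, K3, p.k4)


# ---------------------------------------------------------------------------
# right-hand sides (plain-python; compiled twins live in _kernels)
# ---------------------------------------------------------------------------


def rhs_core(t, y, p: CoreKaiParams):
    """d/dt of (T, ST, S) for the three-phosphoform sequestration model."""
    T, ST, S = y
    f = free_kaiA(max(S, 0.0), p.A_T, p.Kd)
    U = p.C_T - T - ST - S
    return np.array([
        p.k1 * f * U - p.k2 * T,
        p.k2 * T - p.k3 * ST,
        p.k3 * ST - p.k4 * S,
    ])


def rhs_ttfl(t, y, p: TTFLParams):
    """d/dt of (M, U, T, ST, S) for the transcription-coupled model."""
    M, U, T, ST, S = y
    A = free_kaiA(max(S, 0.0), p.A_T, p.Kd)
    if p.mode == "ttfl":
        transcription = (
            p.V_trsp * p.fold_factor / (1.0 + (max(S, 0.0) / p.K_0) ** p.hill_exponent)
        )
    else:
        transcription = p.V_trsp
    return np.array([
        transcription - p.V_m * M,
        p.K_s * M - p.k1 * A * U + p.k4 * S - p.V_d * U,
        p.k1 * A * U - p.k2 * T - p.V_d * T,
        p.k2 * T - p.k3 * ST - p.V_d * ST,
        p.k3 * ST - p.k4 * S - p.V_d * S,
    ])


def repression_function(p):
    """The repression function f(R) matching a chain parameter object."""
    if isinstance(p, NeurosporaParams):
        return lambda R: neurospora_f(R, p)
    if isinstance(p, PhospholockParams):
        return lambda R: phospholock_f(R, p)
    if isinstance(p, KimForgerParams):
        return lambda R: kim_forger_f(R, p.A, p.Kd)
    raise TypeError(f"no repression function for {type(p).__name__}")


def rhs_phospholock(t, y, p):
    """d/dt of (M, r, R) for the activator/repressor transcription chain.

    The repression function dispatches on the parameter type
    (:class:`KimForgerParams`, :class:`PhospholockParams` or
    :class:`NeurosporaParams`).  The repressor-complex balance is
    ``dR/dt = alpha3 * r - beta3 * R`` (production from the repressor
    protein, first-order removal), completing the M -> r -> R chain.
    """
    M, r, R = y
    f = repression_function(p)(max(R, 0.0))
    return np.array([
        p.alpha1 * f - p.beta1 * M,
        p.alpha2 * M - p.beta2 * r,
        p.alpha3 * r - p.beta3 * R,
    ])


def chain_param_vector(p) -> np.ndarray:
    """Flat parameter vector for the compiled chain kernel."""
    if isinstance(p, NeurosporaParams):
        K1, K2, K3 = effective_constants(p)
        return np.array([p.alpha1, p.beta1, p.alpha2, p.beta2, p.alpha3,
                         p.beta3, p.A_T, K1, K2, K3, p.k4])
    if isinstance(p, PhospholockParams):
        K1, K2 = effective_constants(p)
        return np.array([p.alpha1, p.beta1, p.alpha2, p.beta2, p.alpha3,
                         p.beta3, p.A_T, K1, K2, K1, 0.0])
    if isinstance(p, KimForgerParams):
        # fraction = amount / A, folded into alpha1
        return np.array([p.alpha1 / p.A, p.beta1, p.alpha2, p.beta2, p.alpha3,
                         p.beta3, p.A, 1.0, p.Kd, 1.0, 0.0])
    raise TypeError(f"cannot vectorize {type(p).__name__}")
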