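"""Seeded parameter-set samplers for the Monte-Carlo scans.

Every sampler is a pure function of (scheme, seed): identical inputs give
bitwise-identical tables.  A single run seed expands to independent
substreams per pipeline through a name-keyed counter scheme
(:func:`substream`), so pipelines can be re-run independently without
perturbing each other's draws.

Sampling bounds come from the packaged stand-in ranges file
(``data/standin_ranges.yaml``); any entry may be overridden by a user
config.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import simulate

__all__ = [
    "SamplingScheme",
    "load_ranges",
    "substream",
    "sample_core",
    "sample_ttfl",
    "sample_phospholock",
    "apply_phospho_multiplier",
    "sample_until_oscillating",
    "DrawBudgetExceeded",
]

#: multiplier grid for the phosphorylation-strength sweep, strongest
#: dephosphorylation (k2r = 100 k2f) to strongest phosphorylation.
PHOSPHO_MULTIPLIERS = (100.0, 10.0, 1.0, 0.1, 0.01, 0.001, 0.0001)


class DrawBudgetExceeded(RuntimeError):
    """The rejection sampler hit its draw cap before reaching its target."""


def load_ranges(path=None) -> dict:
    """Load sampling schemes; `path` overrides entries of the packaged file."""
    with resources.files("circlock.data").joinpath("standin_ranges.yaml").open() as fh:
        ranges = yaml.safe_load(fh)
    if path is not None:
        with open(path) as fh:
            override = yaml.safe_load(fh) or {}
        for model, spec in override.items():
            base = ranges.setdefault(model, {})
            for kind in ("fixed", "uniform"):
                if kind in spec:
                    base.setdefault(kind, {}).update(spec[kind])
    return ranges


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator keyed by (seed, pipeline name)."""
    key = zlib.crc32(name.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass(frozen=True)
class SamplingScheme:
    """Serializable description of one sampling scheme."""

    model: str
    n: int
    seed: int
    fixed: dict = field(default_factory=dict)
    uniform: dict = field(default_factory=dict)
    derived: dict = field(default_factory=dict)  # name -> "factor*column"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name, (lo, hi) in self.uniform.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"model": self.model, "n": self.n, "seed": self.seed,
                 "fixed": dict(self.fixed),
                 "uniform": {k: list(map(float, v)) for k, v in self.uniform.items()},
                 "derived": dict(self.derived)},
                fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SamplingScheme":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(model=raw["model"], n=raw["n"], seed=raw["seed"],
                   fixed=raw.get("fixed", {}),
                   uniform={k: tuple(v) for k, v in raw.get("uniform", {}).items()},
                   derived=raw.get("derived", {}))

    def draw(self, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
        """Sample the table: uniforms first (stable column order), then fixed
        columns, then derived columns (applied exactly once)."""
        if rng is None:
            rng = substream(self.seed, self.model)
        data = {}
        for name in sorted(self.uniform):
            lo, hi = self.uniform[name]
            data[name] = rng.uniform(lo, hi, self.n)
        for name, value in self.fixed.items():
            data[name] = np.full(self.n, float(value))
        table = pd.DataFrame(data)
        for name, rule in self.derived.items():
            factor, _, column = rule.partition("*")
            table[name] = float(factor) * table[column]
        return table


# ---------------------------------------------------------------------------
# concrete samplers
# ---------------------------------------------------------------------------


def sample_core(Kd: float, n: int, seed: int, ranges: Optional[dict] = None
                ) -> pd.DataFrame:
    """Parameter table for the three-phosphoform model at one Kd.

    k2, k3, k4 are fixed; k1, A_T, C_T are uniform draws.
    """
    if not 0 < Kd <= 1.0:
        raise ValueError(f"Kd out of range: {Kd}")
    spec = (ranges or load_ranges())["core"]
    scheme = SamplingScheme(model="core", n=n, seed=seed,
                            fixed={**spec["fixed"], "Kd": Kd},
                            uniform={k: tuple(v) for k, v in spec["uniform"].items()})
    rng = substream(seed, f"core-kd={Kd:.6g}")
    table = scheme.draw(rng)
    return table[["k1", "k2", "k3", "k4", "Kd", "A_T", "C_T"]]


def sample_ttfl(n: int = 22500, seed: int = 0, ranges: Optional[dict] = None
                ) -> pd.DataFrame:
    """Paired-design table for the transcription-coupled models.

    Only K_s and A_T vary; all other parameters are fixed.  The same table
    serves both transcription modes (the mode is not a column).
    """
    spec = (ranges or load_ranges())["ttfl"]
    scheme = SamplingScheme(model="ttfl", n=n, seed=seed,
                            fixed=spec["fixed"],
                            uniform={k: tuple(v) for k, v in spec["uniform"].items()})
    table = scheme.draw(substream(seed, "ttfl"))
    cols = ["k1", "k2", "k3", "k4", "Kd", "A_T", "V_trsp", "V_m", "K_s",
            "K_0", "V_d"]
    return table[cols]


def sample_phospholock(n: int = 10_000, seed: int = 0, Kd: float = 1.0
                       ) -> pd.DataFrame:
    """Base table for the phospholock chain scans.

    A_T and the six chain rates are uniform on (0, 100); k1f and k2f uniform
    on (0, 1); k3 uniform on (0, 0.1).  The binding constraint k1r = Kd*k1f
    is applied as a derived rule (Kd = 1 gives k1r = k1f exactly).  k2r is
    *not* set here; apply :func:`apply_phospho_multiplier`.
    """
    spec = load_ranges()["phospholock"]
    scheme = SamplingScheme(model="phospholock", n=n, seed=seed,
                            uniform={k: tuple(v) for k, v in spec["uniform"].items()},
                            derived={"k1r": f"{Kd!r}*k1f"})
    table = scheme.draw(substream(seed, f"phospholock-kd={Kd:.6g}"))
    table["Kd"] = Kd
    return table


def apply_phospho_multiplier(table: pd.DataFrame, multiplier: float
                             ) -> pd.DataFrame:
    """Derived table with k2r = multiplier * k2f (all other columns shared)."""
    out = table.copy()
    out["k2r"] = multiplier * out["k2f"]
    return out


# ---------------------------------------------------------------------------
# rejection sampler for oscillating activator-phosphorylation sets
# ---------------------------------------------------------------------------


def _activator_phospho_rows(table: pd.DataFrame, k3_value: float) -> np.ndarray:
    """Chain-kernel parameter rows for the activator-phosphorylation scheme."""
    from .models import NeurosporaParams, chain_param_vector

    rows = np.empty((len(table), 11))
    for i, rec in enumerate(table.itertuples(index=False)):
        p = NeurosporaParams(
            alpha1=rec.alpha1, alpha2=rec.alpha2, alpha3=rec.alpha3,
            beta1=rec.beta1, beta2=rec.beta2, beta3=rec.beta3,
            A_T=rec.A_T, k1f=rec.k1f, k1r=rec.k1r, k2f=rec.k2f,
            k2r=rec.k2r, k3=k3_value, k4f=rec.k4f, k4r=rec.k4r,
        )
        rows[i] = chain_param_vector(p)
    return rows


def sample_until_oscillating(target: int = 100, k3_value: float = 0.0,
                             seed: int = 0, max_draws: int = 200_000,
                             batch: int = 500) -> pd.DataFrame:
    """Rejection-sample activator-phosphorylation chains that oscillate.

    Constraints: Kd = 1e-5 (k1r = 1e-5 * k1f), phosphorylation stronger than
    dephosphorylation in the lock (k2f = 10 * k2r), and symmetric activator
    phospho/dephospho (k4r = k4f).  Draws continue until `target` rows pass
    the event-location oscillation test; the total number of draws is
    recorded in ``DataFrame.attrs["draws"]``.

    Raises :class:`DrawBudgetExceeded` (with the observed acceptance rate)
    if `max_draws` is hit first.
    """
    if target < 1:
        raise ValueError("target must be >= 1")
    spec = load_ranges()["activator_phospho"]
    Kd = float(spec["fixed"]["Kd"])
    rng = substream(seed, f"activator-phospho-k3={k3_value:.6g}")
    accepted = []
    draws = 0
    while sum(len(t) for t in accepted) < target:
        if draws >= max_draws:
            n_acc = sum(len(t) for t in accepted)
            raise DrawBudgetExceeded(
                f"{n_acc}/{target} oscillating sets after {draws} draws "
                f"(acceptance rate {n_acc / draws:.2%})"
            )
        scheme = SamplingScheme(
            model="activator_phospho", n=batch, seed=seed,
            uniform={k: tuple(v) for k, v in spec["uniform"].items()},
        )
        table = scheme.draw(rng)
        table["k1r"] = Kd * table["k1f"]
        table["k2f"] = 10.0 * table["k2r"]
        table["k4r"] = table["k4f"]
        draws += batch
        rows = _activator_phospho_rows(table, k3_value)
        y0 = rng.uniform(0.0, 10.0, size=(batch, 3))
        osc, periods = simulate.batch_classify_events("chain", rows, y0)
        hit = table[osc].copy()
        hit["period"] = periods[osc]
        hit["init_M"], hit["init_r"], hit["init_R"] = y0[osc].T
        accepted.append(hit)
    out = pd.concat(accepted, ignore_index=True).head(target)
    out["k3"] = k3_value
    out.attrs["draws"] = draws
    out.attrs["acceptance_rate"] = float(len(out)) / draws
    return out
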