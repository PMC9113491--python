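"""Indel-length distributions and total event-rate bookkeeping.

Insertion and deletion rates are expressed relative to the substitution
rate.  For a sequence with ``L`` non-gap characters the total rates are

    S = -sum_i q_{x_i x_i} r_i        (substitutions, non-gap sites only)
    I = r_I * (L + 1)                 (insertions)
    D = r_D * (L - 1 + u_D)           (deletions; u_D = mean deletion size)

and the total mutation rate is ``M = S + I + D``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LengthDistribution",
    "IndelModel",
    "sample_length",
    "mean_length",
    "total_event_rates",
]

_KINDS = ("geometric", "negative_binomial", "zipfian", "lavalette")


@dataclass(frozen=True)
class LengthDistribution:
    """Distribution of indel lengths on the positive integers.

    Geometric and (shifted) negative-binomial have unbounded support;
    zipfian (PMF proportional to ``k**-a``) and lavalette (PMF proportional
    to ``((k*m) / (m-k+1))**-a``) are truncated at ``max_len``.
    """

    kind: str
    a: float | None = None          # exponent (zipfian / lavalette)
    max_len: int | None = None      # truncation bound
    p: float | None = None          # success probability (geometric / NB)
    r: float | None = None          # NB dispersion
    _cdf: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown length distribution {self.kind!r}")
        if self.kind in ("zipfian", "lavalette"):
            if self.a is None or self.a <= 0:
                raise ValueError("exponent must be > 0")
            if self.max_len is None or self.max_len < 1:
                raise ValueError("truncation bound must be >= 1")
            object.__setattr__(self, "max_len", int(self.max_len))
            object.__setattr__(self, "_cdf", np.cumsum(self.pmf()))
        elif self.kind == "geometric":
            if self.p is None or not (0 < self.p <= 1):
                raise ValueError("geometric p must be in (0, 1]")
        else:  # negative binomial
            if self.p is None or not (0 < self.p <= 1):
                raise ValueError("negative-binomial p must be in (0, 1]")
            if self.r is None or self.r <= 0:
                raise ValueError("negative-binomial r must be > 0")

    # -- constructors ---------------------------------------------------
    @classmethod
    def geometric(cls, p: float) -> "LengthDistribution":
        return cls(kind="geometric", p=p)

    @classmethod
    def negative_binomial(cls, r: float, p: float) -> "LengthDistribution":
        return cls(kind="negative_binomial", r=r, p=p)

    @classmethod
    def zipfian(cls, a: float = 1.7, max_len: int = 50) -> "LengthDistribution":
        return cls(kind="zipfian", a=a, max_len=max_len)

    @classmethod
    def lavalette(cls, a: float, max_len: int) -> "LengthDistribution":
        return cls(kind="lavalette", a=a, max_len=max_len)

    # -- law ------------------------------------------------------------
    def pmf(self) -> np.ndarray:
        """Exact PMF over support 1..max_len (truncated kinds only)."""
        if self.kind == "zipfian":
            k = np.arange(1, self.max_len + 1, dtype=float)
            w = k ** (-self.a)
        elif self.kind == "lavalette":
            k = np.arange(1, self.max_len + 1, dtype=float)
            w = ((k * self.max_len) / (self.max_len - k + 1)) ** (-self.a)
        else:
            raise ValueError(f"{self.kind} has unbounded support; no finite PMF")
        return w / w.sum()

    def mean(self) -> float:
        """Exact mean length (closed form or direct summation)."""
        if self.kind == "geometric":
            return 1.0 / self.p
        if self.kind == "negative_binomial":
            return 1.0 + self.r * (1.0 - self.p) / self.p
        k = np.arange(1, self.max_len + 1, dtype=float)
        return float(k @ self.pmf())

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw length(s); scalar int when ``size`` is None."""
        if self.kind == "geometric":
            out = rng.geometric(self.p, size=size)
        elif self.kind == "negative_binomial":
            out = rng.negative_binomial(self.r, self.p, size=size) + 1
        else:
            u = rng.random(size)
            out = np.searchsorted(self._cdf, u, side="right") + 1
            out = np.minimum(out, self.max_len)
        return int(out) if size is None else np.asarray(out, dtype=np.int64)


def sample_length(dist: LengthDistribution, rng: np.random.Generator) -> int:
    return dist.sample(rng)


def mean_length(dist: LengthDistribution) -> float:
    return dist.mean()


@dataclass(frozen=True)
class IndelModel:
    """Insertion/deletion rates (relative to substitutions) and length laws."""

    r_ins: float
    r_del: float
    ins_dist: LengthDistribution
    del_dist: LengthDistribution
    u_del: float = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.r_ins) and self.r_ins >= 0):
            raise ValueError("insertion rate must be finite and >= 0")
        if not (np.isfinite(self.r_del) and self.r_del >= 0):
            raise ValueError("deletion rate must be finite and >= 0")
        object.__setattr__(self, "u_del", self.del_dist.mean())

    @classmethod
    def default(cls, r_ins: float, r_del: float) -> "IndelModel":
        """Zipfian(1.7, 50) lengths for both insertions and deletions."""
        z = LengthDistribution.zipfian()
        return cls(r_ins=r_ins, r_del=r_del, ins_dist=z, del_dist=z)


def total_event_rates(states: np.ndarray, rates: np.ndarray, model,
                      indel: IndelModel | None = None) -> dict:
    """Total substitution/insertion/deletion rates for a gapped sequence.

    ``states`` uses integer codes with ``-1`` for gaps; ``rates`` is the
    parallel site-rate vector (gap sites must carry rate 0).
    """
    states = np.asarray(states)
    rates = np.asarray(rates, dtype=float)
    if states.shape != rates.shape:
        raise ValueError("states and rates must have equal length")
    mask = states >= 0
    if np.any(rates[~mask] != 0.0):
        raise ValueError("gap positions must carry rate 0")
    L = int(mask.sum())
    qdiag = np.diag(model.Q)
    S = float(-(qdiag[states[mask]] * rates[mask]).sum()) if L else 0.0
    if indel is None:
        I = D = 0.0
    else:
        I = indel.r_ins * (L + 1)
        D = indel.r_del * (L - 1 + indel.u_del) if indel.r_del > 0 else 0.0
        D = max(D, 0.0)
    return {"S": S, "I": I, "D": D, "M": S + I + D}
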