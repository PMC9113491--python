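"""Substitution models over finite alphabets.

A substitution model is a continuous-time Markov chain with instantaneous
rate matrix ``Q`` and stationary frequencies ``pi``.  Every model built here
is normalized so that rows of ``Q`` sum to zero and the total substitution
rate is one (``sum_x pi_x q_xx = -1``), which makes branch lengths directly
interpretable as expected substitutions per site.

Transition probability matrices ``P(t, r) = expm(Q * t * r)`` are computed
through a cached spectral decomposition for reversible models (on the
symmetrized matrix ``diag(sqrt(pi)) Q diag(1/sqrt(pi))``, guaranteeing real
eigenvalues) and through dense scaling-and-squaring exponentiation
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "Alphabet",
    "DNA",
    "GAP_CODE",
    "SubstitutionModel",
    "TransitionMatrix",
    "build_model",
    "normalize_rate_matrix",
    "sample_root_sequence",
    "parse_model_spec",
    "load_user_matrix",
]

#: Integer code used for the gap character in encoded sequences.
GAP_CODE = -1

# Order of the six exchangeability parameters for 4-state models.
_DNA_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))  # AC AG AT CG CT GT

_FREQ_SUM_TOL = 1e-6
_NEG_PROB_TOL = 1e-12


@dataclass(frozen=True)
class Alphabet:
    """Ordered set of single-character states plus a gap symbol."""

    states: tuple[str, ...]
    gap: str = "-"

    def __post_init__(self) -> None:
        states = tuple(self.states)
        object.__setattr__(self, "states", states)
        if len(states) < 2:
            raise ValueError("alphabet needs at least two states")
        if len(set(states)) != len(states):
            raise ValueError("alphabet states must be unique")
        if any(len(s) != 1 for s in states):
            raise ValueError("alphabet states must be single characters")
        if self.gap in states:
            raise ValueError("gap symbol must not be a state")

    @property
    def size(self) -> int:
        return len(self.states)

    def index(self, symbol: str) -> int:
        try:
            return self.states.index(symbol)
        except ValueError:
            raise ValueError(f"unknown state symbol {symbol!r}") from None

    def encode(self, text: str) -> np.ndarray:
        """Encode a string into int16 state codes (gap -> ``GAP_CODE``)."""
        lut = {s: i for i, s in enumerate(self.states)}
        lut[self.gap] = GAP_CODE
        try:
            return np.array([lut[c] for c in text], dtype=np.int16)
        except KeyError as exc:
            raise ValueError(f"character {exc.args[0]!r} not in alphabet") from None

    def decode(self, codes: np.ndarray) -> str:
        # gap code -1 indexes the trailing gap symbol
        symbols = np.array(list(self.states) + [self.gap], dtype="<U1")
        return "".join(symbols[np.asarray(codes, dtype=np.int64)])


DNA = Alphabet(("A", "C", "G", "T"))


class TransitionMatrix(NamedTuple):
    """A transition probability matrix with the effective distance it encodes."""

    P: np.ndarray
    t_eff: float


class SubstitutionModel:
    """Normalized continuous-time Markov substitution model.

    Parameters
    ----------
    alphabet : Alphabet
    freqs : array-like
        Stationary state frequencies ``pi`` (strictly positive, sum to 1).
    Q : ndarray
        Normalized instantaneous rate matrix (rows sum to 0,
        ``sum pi_x q_xx = -1``).
    reversible : bool
        Whether ``Q`` satisfies detailed balance with respect to ``pi``.
    """

    def __init__(self, alphabet: Alphabet, freqs: np.ndarray, Q: np.ndarray,
                 reversible: bool) -> None:
        freqs = np.asarray(freqs, dtype=float)
        Q = np.asarray(Q, dtype=float)
        if Q.shape != (alphabet.size, alphabet.size):
            raise ValueError("rate matrix shape does not match alphabet")
        if freqs.shape != (alphabet.size,):
            raise ValueError("frequency vector shape does not match alphabet")
        self.alphabet = alphabet
        self.freqs = freqs
        self.Q = Q
        self.reversible = bool(reversible)
        #: number of transition-probability matrices built so far (instrumentation)
        self.n_matrix_builds = 0
        self._eig: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
        self._jump_cdf: np.ndarray | None = None

    # ------------------------------------------------------------------
    @property
    def size(self) -> int:
        return self.alphabet.size

    @property
    def rate_diagonal(self) -> np.ndarray:
        """Diagonal of Q (negative total leave-rates per state)."""
        return np.diag(self.Q)

    @property
    def jump_cdf(self) -> np.ndarray:
        """Per-state cumulative jump distribution q_xy / (-q_xx), y != x."""
        if self._jump_cdf is None:
            J = self.Q.copy()
            np.fill_diagonal(J, 0.0)
            J /= -np.diag(self.Q)[:, None]
            self._jump_cdf = np.cumsum(J, axis=1)
        return self._jump_cdf

    def _eigendecomposition(self):
        """Spectral factorization via the pi-symmetrized matrix (reversible only)."""
        if self._eig is None:
            if not self.reversible:
                raise RuntimeError("eigendecomposition cache is only used for "
                                   "reversible models")
            d = np.sqrt(self.freqs)
            B = self.Q * d[:, None] / d[None, :]
            B = 0.5 * (B + B.T)  # kill round-off asymmetry
            lam, V = np.linalg.eigh(B)
            U = V / d[:, None]
            Uinv = V.T * d[None, :]
            self._eig = (lam, U, Uinv)
        return self._eig

    # ------------------------------------------------------------------
    def transition_matrices(self, t: float, rates: Sequence[float]) -> np.ndarray:
        """Stack of P(t, r) for each rate in ``rates`` (shape ``(m, k, k)``)."""
        rates = np.atleast_1d(np.asarray(rates, dtype=float))
        if not np.isfinite(t) or t < 0:
            raise ValueError("branch length t must be finite and >= 0")
        if not np.all(np.isfinite(rates)) or np.any(rates < 0):
            raise ValueError("site rates must be finite and >= 0")
        tau = t * rates
        if self.reversible:
            lam, U, Uinv = self._eigendecomposition()
            E = np.exp(np.outer(tau, lam))
            P = np.einsum("xj,mj,jy->mxy", U, E, Uinv)
        else:
            P = np.stack([expm(self.Q * ti) for ti in tau])
        P = _clean_probability_rows(P)
        self.n_matrix_builds += len(tau)
        return P

    def transition_matrix(self, t: float, r: float = 1.0) -> TransitionMatrix:
        """P(t, r) = expm(Q * t * r) as a :class:`TransitionMatrix`."""
        P = self.transition_matrices(t, [r])[0]
        return TransitionMatrix(P=P, t_eff=float(t) * float(r))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"SubstitutionModel(k={self.size}, reversible={self.reversible}, "
                f"freqs={np.array2string(self.freqs, precision=4)})")


def _clean_probability_rows(P: np.ndarray) -> np.ndarray:
    """Clamp tiny round-off negatives and renormalize rows to sum exactly 1."""
    low = P.min()
    if low < -_NEG_PROB_TOL:
        raise FloatingPointError(
            f"transition probability {low:.3e} below clamping tolerance")
    np.clip(P, 0.0, None, out=P)
    sums = P.sum(axis=-1, keepdims=True)
    if np.any(np.abs(sums - 1.0) > 1e-8):
        raise FloatingPointError("transition matrix rows far from stochastic")
    P /= sums
    return P


# ----------------------------------------------------------------------
def normalize_rate_matrix(raw_rates: np.ndarray, freqs: np.ndarray,
                          alphabet: Alphabet | None = None) -> SubstitutionModel:
    """Build a normalized model from non-negative off-diagonal rates.

    The diagonal is set to minus the row sum and the matrix rescaled by
    ``c = -1 / sum_x pi_x q_xx`` so the total substitution rate equals one.
    Rows whose off-diagonal entries are all zero (absorbing states) are
    rejected.  Frequencies are renormalized silently if their sum is within
    1e-6 of one, rejected otherwise.
    """
    raw = np.array(raw_rates, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise ValueError("rate matrix must be square")
    k = raw.shape[0]
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (k,):
        raise ValueError("frequency vector length does not match rate matrix")
    if np.any(freqs <= 0):
        raise ValueError("state frequencies must be strictly positive")
    s = freqs.sum()
    if abs(s - 1.0) > _FREQ_SUM_TOL:
        raise ValueError(f"state frequencies sum to {s}, expected 1")
    freqs = freqs / s

    off = raw.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off < 0):
        raise ValueError("off-diagonal rates must be non-negative")
    row = off.sum(axis=1)
    if np.any(row == 0):
        raise ValueError("rate matrix has an absorbing state (all-zero row)")
    Q = off
    np.fill_diagonal(Q, -row)
    mu = -float(freqs @ np.diag(Q))
    Q /= mu

    if alphabet is None:
        if k == 4:
            alphabet = DNA
        else:
            raise ValueError("an Alphabet must be supplied for non-DNA matrices")
    if alphabet.size != k:
        raise ValueError("alphabet size does not match rate matrix")

    flux = freqs[:, None] * Q
    reversible = bool(np.allclose(flux, flux.T, rtol=1e-8, atol=1e-10))
    return SubstitutionModel(alphabet, freqs, Q, reversible)


def _model_from_exchangeabilities(exch: Sequence[float], freqs: np.ndarray,
                                  alphabet: Alphabet) -> SubstitutionModel:
    k = alphabet.size
    n_pairs = k * (k - 1) // 2
    exch = np.asarray(exch, dtype=float)
    if exch.shape != (n_pairs,):
        raise ValueError(f"expected {n_pairs} exchangeabilities, got {len(exch)}")
    if np.any(exch <= 0):
        raise ValueError("exchangeabilities must be strictly positive")
    S = np.zeros((k, k))
    idx = 0
    for i in range(k):
        for j in range(i + 1, k):
            S[i, j] = S[j, i] = exch[idx]
            idx += 1
    raw = S * np.asarray(freqs, dtype=float)[None, :]
    return normalize_rate_matrix(raw, freqs, alphabet)


def _stationary_freqs(raw: np.ndarray) -> np.ndarray:
    """Stationary distribution of the chain with off-diagonal rates ``raw``."""
    Q = np.array(raw, dtype=float)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    # left null vector of Q
    w, V = np.linalg.eig(Q.T)
    i = int(np.argmin(np.abs(w)))
    pi = np.real(V[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def build_model(name: str, params: Sequence[float] | None = None,
                freqs: Sequence[float] | None = None,
                rate_matrix: np.ndarray | None = None,
                alphabet: Alphabet | None = None) -> SubstitutionModel:
    """Construct a named substitution model.

    Supported names: ``JC`` (no parameters), ``K2P`` (one
    transition/transversion ratio, equal frequencies), ``HKY`` (one ratio
    plus frequencies), ``GTR`` (six exchangeabilities plus frequencies) and
    ``USER`` (a full rate matrix, or exchangeabilities plus frequencies over
    an arbitrary alphabet).
    """
    name = name.upper()
    params = tuple(params) if params is not None else ()
    if name not in ("JC", "K2P", "HKY", "GTR", "USER"):
        raise ValueError(f"unknown model name {name!r}")

    if name == "USER":
        alphabet = alphabet or DNA
        if rate_matrix is not None:
            raw = np.asarray(rate_matrix, dtype=float)
            if freqs is None:
                freqs = _stationary_freqs(raw)
            return normalize_rate_matrix(raw, np.asarray(freqs, float), alphabet)
        if freqs is None:
            raise ValueError("USER model needs a rate matrix or "
                             "exchangeabilities plus frequencies")
        return _model_from_exchangeabilities(params, np.asarray(freqs, float),
                                             alphabet)

    alphabet = alphabet or DNA
    if alphabet.size != 4:
        raise ValueError(f"{name} is a 4-state (DNA) model")
    uniform = np.full(4, 0.25)

    if name == "JC":
        if params:
            raise ValueError("JC takes no parameters")
        return _model_from_exchangeabilities(np.ones(6), uniform, alphabet)

    if name == "K2P":
        if len(params) != 1:
            raise ValueError("K2P takes exactly one parameter (kappa)")
        if freqs is not None and not np.allclose(freqs, uniform):
            raise ValueError("K2P assumes equal base frequencies; use HKY")
        kappa = params[0]
        exch = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        return _model_from_exchangeabilities(exch, uniform, alphabet)

    if name == "HKY":
        if len(params) != 1:
            raise ValueError("HKY takes exactly one parameter (kappa)")
        kappa = params[0]
        exch = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        f = uniform if freqs is None else np.asarray(freqs, float)
        return _model_from_exchangeabilities(exch, f, alphabet)

    # GTR
    if len(params) != 6:
        raise ValueError("GTR takes exactly six exchangeabilities")
    f = uniform if freqs is None else np.asarray(freqs, float)
    return _model_from_exchangeabilities(np.asarray(params, float), f, alphabet)


# ----------------------------------------------------------------------
def sample_root_sequence(model: SubstitutionModel, L: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw ``L`` i.i.d. states from the stationary distribution.

    Returns int16 state codes (never gaps).  Deterministic given the
    generator state.
    """
    if L < 1:
        raise ValueError("sequence length must be >= 1")
    cum = np.cumsum(model.freqs)
    codes = np.searchsorted(cum, rng.random(int(L)), side="right")
    return np.minimum(codes, model.size - 1).astype(np.int16)


# ----------------------------------------------------------------------
# Model-string mini grammar:  "GTR{1,2,1.5,0.8,3,1}+F{0.3,0.2,0.2,0.3}+I{0.2}+G4{0.5}"
def split_plus(text: str) -> list[str]:
    """Split a spec string on '+' at brace depth zero."""
    parts, depth, cur = [], 0, []
    for ch in text:
        if ch == "{":
            depth += 1
        elif ch == "}":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced braces in {text!r}")
        if ch == "+" and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    if depth != 0:
        raise ValueError(f"unbalanced braces in {text!r}")
    parts.append("".join(cur))
    return [p for p in parts if p]


def split_braces(token: str) -> tuple[str, str | None]:
    """Split ``HEAD{BODY}`` into (HEAD, BODY); BODY is None without braces."""
    if "{" not in token:
        return token, None
    head, _, rest = token.partition("{")
    if not rest.endswith("}"):
        raise ValueError(f"malformed token {token!r}")
    return head, rest[:-1]


def _floats(body: str | None, token: str) -> list[float]:
    if body is None or body.strip() == "":
        return []
    try:
        return [float(x) for x in body.split(",")]
    except ValueError:
        raise ValueError(f"cannot parse numbers in {token!r}") from None


def load_user_matrix(path: str) -> tuple[Alphabet, np.ndarray]:
    """Load a USER rate matrix from a whitespace-separated text file.

    First non-comment line lists the state symbols, followed by a full
    k x k matrix of rates (diagonal entries are ignored).
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.strip().startswith("#")]
    if not lines:
        raise ValueError(f"empty matrix file {path!r}")
    symbols = tuple(lines[0].split())
    alphabet = Alphabet(symbols)
    k = len(symbols)
    if len(lines) != k + 1:
        raise ValueError(f"expected {k} matrix rows in {path!r}")
    raw = np.array([[float(x) for x in ln.split()] for ln in lines[1:]])
    if raw.shape != (k, k):
        raise ValueError(f"matrix in {path!r} is not {k}x{k}")
    return alphabet, raw


def parse_model_spec(text: str):
    """Parse a full model string into a (SubstitutionModel, RateModel) pair."""
    from . import site_rates  # deferred to avoid an import cycle

    tokens = split_plus(text.strip())
    if not tokens:
        raise ValueError("empty model specification")
    head, body = split_braces(tokens[0])
    head = head.upper()

    freqs = None
    rate_tokens = []
    user_path = None
    for tok in tokens[1:]:
        h, b = split_braces(tok)
        if h.upper() == "F":
            freqs = _floats(b, tok)
            if not freqs:
                raise ValueError(f"empty frequency list in {tok!r}")
        else:
            rate_tokens.append(tok)

    if head == "USER":
        if body is None:
            raise ValueError("USER model requires a matrix file: USER{path}")
        user_path = body
        alphabet, raw = load_user_matrix(user_path)
        model = build_model("USER", rate_matrix=raw, freqs=freqs,
                            alphabet=alphabet)
    else:
        params = _floats(body, tokens[0])
        model = build_model(head, params=params, freqs=freqs)

    rate_model = site_rates.parse_rate_components(rate_tokens)
    return model, rate_model
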