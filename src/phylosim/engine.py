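"""Sequence evolution along a tree.

Two per-branch algorithms are provided: an event-based Gillespie simulation
driven by the total mutation rate (substitutions, insertions, deletions)
and a per-site transition-probability sampler, plus an adaptive per-branch
switch between them based on the product of sequence length and branch
length.  The tree traversal stores at most a depth-bounded number of
sequences, streams tips when possible, and reconciles insertion events into
global alignment columns so that all output rows have equal length.

Two alignment assemblers exist for simulations with indels: the production
event-log assembler, which splices new column identifiers into a global
column order at event time, and a reference "naive" assembler, which
physically inserts gap stretches into every stored sequence at event time.
Both run the same per-branch code on the same RNG streams and must produce
byte-identical alignments.
"""

from __future__ import annotations

import enum
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sstats

from .indels import IndelModel, total_event_rates
from .models import GAP_CODE, SubstitutionModel, sample_root_sequence
from .site_rates import RateModel, sample_site_rates
from .trees import Tree

__all__ = [
    "Approach",
    "SequenceState",
    "InsertionEvent",
    "BranchResult",
    "SimulationConfig",
    "DISCRETE_SWITCH",
    "CONTINUOUS_SWITCH",
    "choose_approach",
    "gillespie_branch",
    "probmatrix_branch",
    "simulate_alignment",
    "equivalence_check",
    "calibrate_switching",
]

#: Default L*t switching constants for the adaptive approach.
DISCRETE_SWITCH = 2.226
CONTINUOUS_SWITCH = 17.307

# Incremental rate totals are refreshed from scratch this often to cap drift.
_REFRESH_EVERY = 1_000_000


class Approach(enum.Enum):
    RATE_MATRIX = "rate"
    PROB_MATRIX = "prob"
    ADAPTIVE = "adaptive"


@dataclass
class SequenceState:
    """A gapped sequence (int codes, -1 for gaps) with parallel site rates."""

    states: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int16)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.states.shape != self.rates.shape:
            raise ValueError("states and rates must have equal length")
        if np.any(self.rates[self.states < 0] != 0.0):
            raise ValueError("gap positions must carry rate 0")

    @property
    def n_sites(self) -> int:
        """Current alignment width (gaps included)."""
        return len(self.states)

    @property
    def n_residues(self) -> int:
        """Number of non-gap characters."""
        return int((self.states >= 0).sum())

    def copy(self) -> "SequenceState":
        return SequenceState(self.states.copy(), self.rates.copy())

    def to_string(self, alphabet) -> str:
        return alphabet.decode(self.states)

    def totals(self, model: SubstitutionModel,
               indel: IndelModel | None = None) -> dict:
        return total_event_rates(self.states, self.rates, model, indel)


@dataclass(frozen=True)
class InsertionEvent:
    """One insertion realized on a branch.

    ``slot`` is the chosen non-gap slot (0-based, ``slot == L`` means
    append); ``local_index`` is the splice index in the evolving child
    vector at event time.
    """

    node_id: int
    slot: int
    length: int
    local_index: int
    append: bool


@dataclass
class BranchResult:
    state: SequenceState
    insertions: list[InsertionEvent]
    n_substitutions: int = 0
    n_insertions: int = 0
    n_deletions: int = 0


@dataclass
class SimulationConfig:
    """Run-level settings for :func:`simulate_alignment`."""

    length: int
    approach: Approach = Approach.ADAPTIVE
    switch_discrete: float = DISCRETE_SWITCH
    switch_continuous: float = CONTINUOUS_SWITCH
    seed: int = 0
    n_alignments: int = 1
    write_ancestral: bool = False
    streaming: bool = True
    root_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("root sequence length must be >= 1")
        if self.switch_discrete <= 0 or self.switch_continuous <= 0:
            raise ValueError("switching thresholds must be > 0")
        if self.write_ancestral and self.streaming:
            # ancestral output needs buffered rows
            self.streaming = False


def choose_approach(L: int, t: float, rate_model: RateModel | None,
                    config: SimulationConfig | None = None) -> Approach:
    """Pick the per-branch algorithm from the L*t product.

    Returns RATE_MATRIX iff ``L*t`` is strictly below the threshold: 2.226
    for homogeneous/discrete rate models, 17.307 for continuous Gamma.
    Ties use the probability-matrix approach.
    """
    if L < 1:
        raise ValueError("sequence length must be >= 1")
    if t < 0:
        raise ValueError("branch length must be >= 0")
    continuous = rate_model is not None and rate_model.is_continuous
    if config is not None:
        thr = config.switch_continuous if continuous else config.switch_discrete
    else:
        thr = CONTINUOUS_SWITCH if continuous else DISCRETE_SWITCH
    return Approach.RATE_MATRIX if L * t < thr else Approach.PROB_MATRIX


# ----------------------------------------------------------------------
def gillespie_branch(state: SequenceState, t: float, model: SubstitutionModel,
                     rate_model: RateModel | None = None,
                     indel: IndelModel | None = None,
                     rng: np.random.Generator | None = None,
                     pin_substitutions: bool = False,
                     on_insert=None, node_id: int = -1) -> BranchResult:
    """Evolve one branch by the event-based (Gillespie) algorithm.

    Waiting times are exponential with mean ``1/M``; each event is a
    substitution, insertion or deletion with probabilities ``S/M``, ``I/M``,
    ``D/M``.  With ``pin_substitutions`` the total substitution rate is held
    at zero (used for the indel phase of the probability-matrix approach).

    ``on_insert(local_index, length, append)`` is called after each
    insertion has been spliced into the evolving child vector, so an
    assembler can keep global column bookkeeping in sync.
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if rng is None:
        raise ValueError("an explicit RNG is required")
    rate_model = rate_model or RateModel.constant()

    states = state.states.copy()
    rates = state.rates.copy()
    qdiag = model.rate_diagonal  # negative leave-rates
    jump_cdf = model.jump_cdf
    k = model.size

    mask = states >= 0
    L = int(mask.sum())
    if pin_substitutions:
        w = None
        S = 0.0
    else:
        w = np.zeros(len(states))
        w[mask] = -qdiag[states[mask]] * rates[mask]
        S = float(w.sum())

    has_indel = indel is not None and (indel.r_ins > 0 or indel.r_del > 0)
    if has_indel:
        r_ins, r_del, u_del = indel.r_ins, indel.r_del, indel.u_del
        pi_cdf = np.cumsum(model.freqs)

    insertions: list[InsertionEvent] = []
    n_sub = n_ins = n_del = n_events = 0
    t_rem = float(t)

    while True:
        if has_indel:
            I = r_ins * (L + 1)
            D = r_del * (L - 1 + u_del) if r_del > 0 else 0.0
        else:
            I = D = 0.0
        M = S + I + D
        if M <= 0:
            break
        waiting = rng.exponential(1.0 / M)
        if waiting > t_rem:
            break
        t_rem -= waiting

        u = rng.random() * M
        if u < S:
            # --- substitution -----------------------------------------
            if L == 0:
                break  # all-gap sequence: end the branch
            target = rng.random() * S
            cw = np.cumsum(w)
            i = int(np.searchsorted(cw, target, side="right"))
            i = min(i, len(states) - 1)
            while states[i] < 0:  # numeric edge: never land on a gap
                i -= 1
            y = int(states[i])
            z = int(np.searchsorted(jump_cdf[y], rng.random(), side="right"))
            z = min(z, k - 1)
            S += (qdiag[y] - qdiag[z]) * rates[i]
            w[i] = -qdiag[z] * rates[i]
            states[i] = z
            n_sub += 1
        elif u < S + I:
            # --- insertion --------------------------------------------
            slot = int(rng.integers(L + 1))
            j = indel.ins_dist.sample(rng)
            codes = np.searchsorted(pi_cdf, rng.random(j), side="right")
            codes = np.minimum(codes, k - 1).astype(np.int16)
            new_rates = sample_site_rates(rate_model, j, rng).rates
            if slot == L:
                idx = len(states)
                append = True
            else:
                idx = int(np.flatnonzero(states >= 0)[slot])
                append = False
            states = np.insert(states, idx, codes)
            rates = np.insert(rates, idx, new_rates)
            if not pin_substitutions:
                new_w = -qdiag[codes] * new_rates
                w = np.insert(w, idx, new_w)
                S += float(new_w.sum())
            L += j
            insertions.append(InsertionEvent(node_id=node_id, slot=slot,
                                             length=j, local_index=idx,
                                             append=append))
            if on_insert is not None:
                on_insert(idx, j, append)
            n_ins += 1
        else:
            # --- deletion ---------------------------------------------
            j = indel.del_dist.sample(rng)
            start = int(rng.integers(L))
            pos = np.flatnonzero(states >= 0)[start:start + j]
            if not pin_substitutions:
                S -= float(w[pos].sum())
                w[pos] = 0.0
            states[pos] = GAP_CODE
            rates[pos] = 0.0
            L -= len(pos)
            n_del += 1
            if L == 0:
                break  # descendants inherit the all-gap sequence

        n_events += 1
        if n_events % _REFRESH_EVERY == 0 and not pin_substitutions:
            mask = states >= 0
            w = np.zeros(len(states))
            w[mask] = -qdiag[states[mask]] * rates[mask]
            S = float(w.sum())

    out = SequenceState(states, rates)
    return BranchResult(state=out, insertions=insertions, n_substitutions=n_sub,
                        n_insertions=n_ins, n_deletions=n_del)


def probmatrix_branch(state: SequenceState, t: float, model: SubstitutionModel,
                      rate_model: RateModel | None = None,
                      indel: IndelModel | None = None,
                      rng: np.random.Generator | None = None,
                      on_insert=None, node_id: int = -1) -> BranchResult:
    """Evolve one branch by per-site sampling from P(t, r_i) = expm(Q t r_i).

    With a discrete rate model only one transition matrix per distinct rate
    is built; gap and rate-zero sites are left untouched.  Indels are then
    simulated by the Gillespie algorithm with the substitution rate pinned
    at zero.
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if rng is None:
        raise ValueError("an explicit RNG is required")
    states = state.states.copy()
    rates = state.rates

    n_changed = 0
    active = np.flatnonzero((states >= 0) & (rates > 0))
    if t > 0 and len(active):
        r = rates[active]
        uniq, inv = np.unique(r, return_inverse=True)
        P = model.transition_matrices(t, uniq)
        rows = P[inv, states[active], :]
        cum = np.cumsum(rows, axis=1)
        u = rng.random(len(active))
        new = (cum <= u[:, None]).sum(axis=1).astype(np.int16)
        new = np.minimum(new, model.size - 1)
        n_changed = int((new != states[active]).sum())
        states[active] = new

    out = SequenceState(states, rates.copy())
    result = BranchResult(state=out, insertions=[], n_substitutions=n_changed)
    if indel is not None and (indel.r_ins > 0 or indel.r_del > 0):
        sub = gillespie_branch(out, t, model, rate_model, indel, rng,
                               pin_substitutions=True, on_insert=on_insert,
                               node_id=node_id)
        result.state = sub.state
        result.insertions = sub.insertions
        result.n_insertions = sub.n_insertions
        result.n_deletions = sub.n_deletions
    return result


# ----------------------------------------------------------------------
# Alignment assemblers.
class _EventLogAssembler:
    """Tracks global alignment columns via spliceable column identifiers.

    Each lineage stores only the columns it knows about; at event time the
    new columns are spliced into a single global column order, and rows are
    materialized (gap-filling foreign columns) once the traversal ends.
    """

    def __init__(self, length: int) -> None:
        self.global_cols: list[int] = list(range(length))
        self.col_pos = {c: i for c, i in zip(self.global_cols,
                                             range(length))}
        self.next_id = length
        self.ids: dict[int, list[int]] = {}
        self.rows: list[tuple[str, list[int], np.ndarray]] = []

    def root_context(self, node_id: int, length: int) -> None:
        self.ids[node_id] = list(range(length))

    def child_context(self, parent_id: int, child_id: int,
                      parent_state: SequenceState):
        child_ids = list(self.ids[parent_id])
        self.ids[child_id] = child_ids

        def on_insert(local_idx: int, j: int, append: bool) -> None:
            new_ids = list(range(self.next_id, self.next_id + j))
            self.next_id += j
            if append:
                gpos = len(self.global_cols)
            else:
                gpos = self.col_pos[child_ids[local_idx]]
            self.global_cols[gpos:gpos] = new_ids
            for off, cid in enumerate(new_ids):
                self.col_pos[cid] = gpos + off
            for cid in self.global_cols[gpos + j:]:
                self.col_pos[cid] += j
            child_ids[local_idx:local_idx] = new_ids

        return parent_state.copy(), on_insert

    def store_row(self, name: str, node_id: int, state: SequenceState) -> None:
        self.rows.append((name, self.ids[node_id], state.states))

    def release(self, node_id: int) -> None:
        self.ids.pop(node_id, None)

    def finalize(self, alphabet) -> list[tuple[str, str]]:
        width = len(self.global_cols)
        out = []
        for name, ids, codes in self.rows:
            row = np.full(width, GAP_CODE, dtype=np.int16)
            pos = np.fromiter((self.col_pos[c] for c in ids), dtype=np.int64,
                              count=len(ids))
            row[pos] = codes
            out.append((name, alphabet.decode(row)))
        return out


class _NaiveAssembler:
    """Reference assembler: physically pads every stored sequence at event
    time.  Keeps all sequences; used to validate the event-log assembler."""

    def __init__(self, length: int) -> None:
        self.registry: dict[int, SequenceState] = {}
        self.names: dict[int, str] = {}
        self.row_order: list[int] = []

    def root_context(self, node_id: int, length: int) -> None:
        pass

    def child_context(self, parent_id: int, child_id: int,
                      parent_state: SequenceState):
        def on_insert(local_idx: int, j: int, append: bool) -> None:
            gap_codes = np.full(j, GAP_CODE, dtype=np.int16)
            gap_rates = np.zeros(j)
            for st in self.registry.values():
                st.states = np.insert(st.states, local_idx, gap_codes)
                st.rates = np.insert(st.rates, local_idx, gap_rates)

        return parent_state.copy(), on_insert

    def register(self, node_id: int, state: SequenceState) -> None:
        self.registry[node_id] = state

    def store_row(self, name: str, node_id: int, state: SequenceState) -> None:
        self.registry[node_id] = state
        self.names[node_id] = name
        self.row_order.append(node_id)

    def release(self, node_id: int) -> None:
        pass  # the reference keeps everything

    def finalize(self, alphabet) -> list[tuple[str, str]]:
        return [(self.names[i], self.registry[i].to_string(alphabet))
                for i in self.row_order]


# ----------------------------------------------------------------------
def _branch_rng(seed: int, rep: int, node_id: int) -> np.random.Generator:
    """Deterministic per-branch stream so traversal order cannot matter."""
    return np.random.default_rng(np.random.SeedSequence([seed, rep, node_id]))


def _run_branch(approach: Approach, *args, **kwargs) -> BranchResult:
    op = gillespie_branch if approach is Approach.RATE_MATRIX \
        else probmatrix_branch
    return op(*args, **kwargs)


def simulate_alignment(tree: Tree, model: SubstitutionModel,
                       rate_model: RateModel | None = None,
                       indel: IndelModel | None = None,
                       config: SimulationConfig | None = None,
                       sink=None, rep: int = 0,
                       assembler: str = "eventlog") -> dict:
    """Simulate one alignment along ``tree``; returns a summary record.

    The root sequence is drawn from the stationary distribution (or taken
    from ``config.root_sequence``), each branch is evolved by the configured
    approach, and internal-node storage is released as soon as all children
    are generated.  Without indels and with ``streaming`` on, tips are
    written to ``sink`` and freed immediately; otherwise rows are buffered
    and reconciled into equal-length alignment rows.

    Summary keys: ``rows`` (when not streamed to a sink), ``width``,
    ``n_tips``, ``approach_counts``, ``peak_live`` and event tallies.
    """
    if config is None:
        raise ValueError("a SimulationConfig is required")
    rate_model = rate_model or RateModel.constant()
    tree.validate()
    if not tree.has_branch_lengths():
        raise ValueError("tree is missing branch lengths; supply them or a "
                         "branch-length distribution before simulating")
    tree.index_nodes()

    use_indel = indel is not None and (indel.r_ins > 0 or indel.r_del > 0)
    streaming = (config.streaming and not use_indel
                 and not config.write_ancestral and sink is not None)

    root_rng = _branch_rng(config.seed, rep, tree.root.id)
    if config.root_sequence is not None:
        codes = model.alphabet.encode(config.root_sequence)
        if np.any(codes < 0):
            raise ValueError("user root sequence must not contain gaps")
        L0 = len(codes)
    else:
        L0 = config.length
        codes = sample_root_sequence(model, L0, root_rng)
    root_state = SequenceState(codes,
                               sample_site_rates(rate_model, L0, root_rng).rates)

    asm = None
    if use_indel:
        asm = _NaiveAssembler(L0) if assembler == "naive" \
            else _EventLogAssembler(L0)
        asm.root_context(tree.root.id, L0)
        if assembler == "naive":
            asm.register(tree.root.id, root_state)

    live = 1
    peak_live = 1
    approach_counts = {Approach.RATE_MATRIX: 0, Approach.PROB_MATRIX: 0}
    totals = {"n_substitutions": 0, "n_insertions": 0, "n_deletions": 0}
    rows: list[tuple[str, str]] = []
    n_tips = 0

    def node_name(node) -> str:
        return node.name if node.name else f"N{node.id}"

    seqs = {tree.root.id: root_state}
    stack = [tree.root]
    while stack:
        node = stack.pop()
        state = seqs[node.id]
        internal_children = []
        for child in node.children:
            rng = _branch_rng(config.seed, rep, child.id)
            t = child.length
            L_parent = state.n_residues
            if L_parent == 0:
                # all-gap parent: the branch is inert, the child inherits
                child_state, on_insert = (state.copy(), None) if asm is None \
                    else asm.child_context(node.id, child.id, state)
                result = BranchResult(state=child_state, insertions=[])
                approach = None
            else:
                if config.approach is Approach.ADAPTIVE:
                    approach = choose_approach(L_parent, t, rate_model, config)
                else:
                    approach = config.approach
                if asm is None:
                    child_state, on_insert = state.copy(), None
                else:
                    child_state, on_insert = asm.child_context(node.id,
                                                               child.id, state)
                result = _run_branch(
                    approach, child_state, t, model, rate_model,
                    indel if use_indel else None, rng,
                    on_insert=on_insert, node_id=child.id)
                approach_counts[approach] += 1
            totals["n_substitutions"] += result.n_substitutions
            totals["n_insertions"] += result.n_insertions
            totals["n_deletions"] += result.n_deletions

            live += 1
            peak_live = max(peak_live, live)
            if child.is_tip:
                n_tips += 1
                if streaming:
                    sink.write_row(node_name(child),
                                   result.state.to_string(model.alphabet))
                elif asm is None:
                    rows.append((node_name(child),
                                 result.state.to_string(model.alphabet)))
                else:
                    asm.store_row(node_name(child), child.id, result.state)
                live -= 1
            else:
                seqs[child.id] = result.state
                if isinstance(asm, _NaiveAssembler):
                    asm.register(child.id, result.state)
                internal_children.append(child)

        # all children generated: release this node's sequence
        if config.write_ancestral:
            if asm is None:
                rows.append((node_name(node), state.to_string(model.alphabet)))
            else:
                asm.store_row(node_name(node), node.id, state)
        del seqs[node.id]
        if asm is not None:
            asm.release(node.id)
        live -= 1
        stack.extend(reversed(internal_children))

    if asm is not None:
        rows = asm.finalize(model.alphabet)

    if rows and sink is not None and not streaming:
        widths = {len(s) for _, s in rows}
        if len(widths) != 1:
            raise AssertionError("assembler produced ragged rows")
        if hasattr(sink, "start"):
            sink.start(len(rows), len(rows[0][1]))
        for name, seq in rows:
            sink.write_row(name, seq)

    width = len(rows[0][1]) if rows else L0
    return {
        "rows": rows,
        "width": width,
        "n_tips": n_tips,
        "approach_counts": {a.value: c for a, c in approach_counts.items()},
        "peak_live": peak_live,
        **totals,
    }


# ----------------------------------------------------------------------
def equivalence_check(model: SubstitutionModel, rate_model: RateModel | None,
                      L: int, t: float, n_reps: int,
                      rng: np.random.Generator,
                      model_b: SubstitutionModel | None = None,
                      min_expected: float = 5.0) -> dict:
    """Chi-square homogeneity test between the two branch algorithms.

    Simulates ``n_reps`` child sequences per approach from the same parent
    (no indels), tabulates child-state counts per parent state, and sums the
    per-parent-state chi-square homogeneity statistics.  ``model_b`` lets a
    deliberately corrupted model drive the second arm (negative control).
    Sites with rate zero are excluded (their outcome is deterministic).
    """
    rate_model = rate_model or RateModel.constant()
    parent_codes = sample_root_sequence(model, L, rng)
    parent_rates = sample_site_rates(rate_model, L, rng).rates
    parent = SequenceState(parent_codes, parent_rates)
    active = parent.rates > 0
    px = parent.states[active]

    k = model.size
    counts = np.zeros((2, k, k), dtype=np.int64)
    arms = ((gillespie_branch, model), (probmatrix_branch, model_b or model))
    for arm, (op, m) in enumerate(arms):
        arm_seed = int(rng.integers(2 ** 62))
        for r in range(n_reps):
            arng = np.random.default_rng(np.random.SeedSequence([arm_seed, r]))
            res = op(parent, t, m, rate_model, None, arng)
            np.add.at(counts[arm], (px, res.state.states[active]), 1)

    stat = 0.0
    dof = 0
    for x in range(k):
        table = counts[:, x, :]
        cols = table.sum(axis=0) > 0
        sub = table[:, cols]
        if sub.shape[1] < 2 or sub.sum(axis=1).min() == 0:
            continue  # degenerate (e.g. t == 0): nothing to compare
        res = _sstats.chi2_contingency(sub, correction=False)
        if res.expected_freq.min() < min_expected:
            raise ValueError("n_reps too small for chi-square validity "
                             f"(min expected cell {res.expected_freq.min():.2f})")
        stat += res.statistic
        dof += res.dof
    p_value = float(_sstats.chi2.sf(stat, dof)) if dof > 0 else 1.0
    return {"statistic": float(stat), "dof": int(dof), "p_value": p_value,
            "counts": counts, "degenerate": dof == 0}


# ----------------------------------------------------------------------
def _default_timer(model: SubstitutionModel, rate_model: RateModel,
                   rng: np.random.Generator):
    """Wall-clock timer for one branch simulation (hardware dependent)."""

    def timer(approach: str, L: int, t: float) -> float:
        codes = sample_root_sequence(model, L, rng)
        rates = sample_site_rates(rate_model, L, rng).rates
        state = SequenceState(codes, rates)
        op = gillespie_branch if approach == "rate" else probmatrix_branch
        start = time.perf_counter()
        op(state, t, model, rate_model, None, rng)
        return time.perf_counter() - start

    return timer


def calibrate_switching(model: SubstitutionModel,
                        rate_model: RateModel | None,
                        lengths, rng: np.random.Generator | None = None,
                        timer=None, t_bounds=(1e-3, 2.0),
                        iterations: int = 30, max_widen: int = 8) -> dict:
    """Estimate the L*t crossover constant between the two branch algorithms.

    For each sequence length, binary-search the branch length at which the
    measured runtimes cross, then least-square fit ``t* = C / L`` through
    the origin and return ``C``.  Results are informational only: defaults
    stay at the published constants and are never overridden silently.
    """
    rate_model = rate_model or RateModel.constant()
    if timer is None:
        if rng is None:
            raise ValueError("an RNG is required for wall-clock calibration")
        timer = _default_timer(model, rate_model, rng)

    crossovers = []
    for L in lengths:
        lo, hi = float(t_bounds[0]), float(t_bounds[1])
        diff = lambda t: timer("rate", int(L), t) - timer("prob", int(L), t)
        f_lo, f_hi = diff(lo), diff(hi)
        widened = 0
        while f_lo > 0 and widened < max_widen:
            lo /= 4.0
            f_lo = diff(lo)
            widened += 1
        while f_hi < 0 and widened < max_widen:
            hi *= 4.0
            f_hi = diff(hi)
            widened += 1
        if f_lo > 0 or f_hi < 0:
            warnings.warn(f"timings do not bracket a crossover for L={L}; "
                          "skipping")
            continue
        for _ in range(iterations):
            mid = 0.5 * (lo + hi)
            if diff(mid) < 0:
                lo = mid
            else:
                hi = mid
        crossovers.append((int(L), 0.5 * (lo + hi)))

    if not crossovers:
        raise RuntimeError("no usable crossover points")
    num = sum(t / L for L, t in crossovers)
    den = sum(1.0 / (L * L) for L, _ in crossovers)
    constant = num / den
    return {"crossovers": crossovers, "constant": constant}
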