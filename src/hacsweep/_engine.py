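"""Structured-coalescent sweep engine.

Simulates the genealogy of a sample drawn while a positively selected
allele, currently at population frequency ``f``, is sweeping through a
panmictic diploid population of effective size ``N``.  The model is the
two-background structured coalescent conditioned on the selected allele's
frequency trajectory:

1.  A frequency trajectory ``x(t)`` is generated backwards in time from
    ``x(0) = f`` down to the mutation's origin at ``1/(2N)``.  The time
    reversal of the path since its origin is the forward Wright-Fisher
    diffusion conditioned on loss: Euler steps with drift
    ``-s·x(1-x)·coth(2Ns·(1-x))`` (s→0 limit ``-x/2N``, the neutral
    allele-age process) and diffusion variance ``x(1-x)/2N`` per
    generation; the deterministic variant is the logistic decline.
2.  Sample lineages live in the derived (beneficial) or ancestral
    background.  Within-background pairs coalesce at per-generation rate
    ``1/(2N·x)`` and ``1/(2N·(1-x))``; at a recombination event the piece of
    the lineage that does not contain the selected site joins the derived
    background with probability ``x(t)``.
3.  When the trajectory is absorbed at the origin, all remaining derived
    lineages merge into the founding chromosome, which joins the ancestral
    background; the process continues as a standard neutral coalescent with
    recombination until every chromosome interval has fully coalesced.

Neutral mutations are dropped onto lineage ancestral material during the
walk at locus rate ``Θ/(4N)`` per generation, which is equivalent to
placing Poisson mutations on the branches of every marginal tree
(infinite-sites, continuous positions).  Each lineage records, per
chromosome interval, the bitmask of present-day samples inheriting that
interval through it, so a mutation immediately knows its carriers and no
marginal-tree extraction is needed; intervals whose mask reaches the full
sample have found their MRCA and are pruned.

Internal module; :mod:`hacsweep.simulate` is the public surface.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["RecombinationMap", "sweep_trajectory", "simulate_sweep_replicate"]


class TrajectoryError(RuntimeError):
    pass


class RecombinationMap:
    """Piecewise-constant per-bp, per-generation recombination rate on [0, L]."""

    def __init__(self, breaks, rates):
        self.breaks = np.asarray(breaks, dtype=float)
        self.rates = np.asarray(rates, dtype=float)
        if self.breaks.size != self.rates.size + 1:
            raise ValueError("need len(breaks) == len(rates) + 1")
        self.cum = np.concatenate([[0.0], np.cumsum(np.diff(self.breaks) * self.rates)])
        self.total = float(self.cum[-1])
        self._br = self.breaks.tolist()
        self._cm = self.cum.tolist()
        self._rt = self.rates.tolist()

    @classmethod
    def uniform_with_hotspots(
        cls,
        rho: float,
        N: float,
        L: float,
        hotspots: tuple[tuple[float, float], ...] = (),
        hotspot_width: float = 2000.0,
    ) -> "RecombinationMap":
        """Background per-bp rate ρ/(4N·L) with multiplier intervals.

        ``hotspots`` are (start_bp, multiplier) pairs; each spans
        [start, start + hotspot_width) at multiplier × the background rate.
        """
        base = rho / (4.0 * N * L)
        cuts = {0.0, float(L)}
        for start, _ in hotspots:
            cuts.add(float(start))
            cuts.add(float(min(start + hotspot_width, L)))
        breaks = np.array(sorted(cuts))
        rates = np.full(breaks.size - 1, base)
        for start, mult in hotspots:
            lo, hi = float(start), float(min(start + hotspot_width, L))
            sel = (breaks[:-1] >= lo) & (breaks[:-1] < hi)
            rates[sel] = base * mult
        return cls(breaks, rates)

    def _cum_at(self, x: float) -> float:
        # piecewise-linear cumulative map; maps have a handful of pieces so a
        # linear scan beats array machinery in the event loop
        br, cm, rt = self._br, self._cm, self._rt
        for i in range(len(rt)):
            if x <= br[i + 1]:
                return cm[i] + (x - br[i]) * rt[i]
        return cm[-1]

    def map_length(self, a: float, b: float) -> float:
        return self._cum_at(b) - self._cum_at(a)

    def sample_breakpoint(self, a: float, b: float, u: float) -> float:
        """Position within (a, b) at map-length fraction ``u`` of the span."""
        target = self._cum_at(a) + u * (self._cum_at(b) - self._cum_at(a))
        br, cm, rt = self._br, self._cm, self._rt
        for i in range(len(rt)):
            if target <= cm[i + 1]:
                if rt[i] == 0:
                    return br[i + 1]
                return br[i] + (target - cm[i]) / rt[i]
        return br[-1]


def _coth(y: float) -> float:
    if y > 20.0:
        return 1.0
    if y < 1e-8:
        return 1.0 / y
    return math.cosh(y) / math.sinh(y)


def sweep_trajectory(
    rng: np.random.Generator,
    f: float,
    s: float,
    N: float,
    stochastic: bool = True,
    dt: float | None = None,
    max_generations: float = 400_000.0,
    max_restarts: int = 100,
) -> tuple[np.ndarray, float]:
    """Backward-time frequency trajectory of the selected allele.

    Starts at ``x = f`` (the present) and runs backwards until absorption at
    the origin frequency ``1/(2N)``.  Returns ``(x, dt)`` where ``x[j]`` is
    the frequency during generations ``[j·dt, (j+1)·dt)`` ago.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("current frequency f must be in (0,1)")
    x0 = 1.0 / (2.0 * N)
    if dt is None:
        dt = min(1.0, 0.05 / s) if s > 0 else 1.0
    alpha = 2.0 * N * s
    if not stochastic:
        if s <= 0:
            raise ValueError("deterministic trajectory requires s > 0")
        t_end = math.log((f / (1.0 - f)) * ((1.0 - x0) / x0)) / s
        t = np.arange(max(2, int(math.ceil(t_end / dt)))) * dt
        x = f / (f + (1.0 - f) * np.exp(s * t))
        return np.maximum(x, x0), dt
    max_steps = int(max_generations / dt)
    for _ in range(max_restarts):
        xs = [f]
        x = f
        for _ in range(max_steps):
            # time reversal of the path since origin = the forward diffusion
            # conditioned on loss: drift −s·x(1−x)·coth(2Ns(1−x)), whose
            # s→0 limit −x/(2N) is the Maruyama-Kimura neutral allele-age
            # process and whose interior behaviour is the logistic decline
            if s > 0:
                drift = -s * x * (1.0 - x) * _coth(alpha * (1.0 - x))
            else:
                drift = -x / (2.0 * N)  # neutral allele, conditioned on origin
            noise = math.sqrt(max(x * (1.0 - x), 0.0) * dt / (2.0 * N))
            x = x + drift * dt + noise * rng.standard_normal()
            if x <= x0:
                return np.asarray(xs), dt
            x = min(x, 1.0 - x0)
            xs.append(x)
    raise TrajectoryError(
        f"trajectory failed to reach the origin within {max_generations} generations"
    )


class _Lineage:
    __slots__ = ("segs", "bg", "mat", "span_rate")

    def __init__(self, segs, bg, recomb_map, mat=None):
        self.segs = segs  # sorted, disjoint [left, right, carrier_bitmask]
        self.bg = bg  # 1 = derived background, 0 = ancestral
        self.mat = sum(r - l for l, r, _ in segs) if mat is None else mat
        if segs and recomb_map.total > 0:
            self.span_rate = recomb_map.map_length(segs[0][0], segs[-1][1])
        else:
            self.span_rate = 0.0


def _merge_segments(a, b, full_mask):
    """Union of two carrier-interval lists, OR-ing masks on overlaps and
    pruning intervals whose mask reaches the full sample (MRCA found).

    Two-pointer sweep over interval boundaries; returns (segments, material
    length) so callers avoid re-measuring."""
    out = []
    mat = 0.0
    na, nb = len(a), len(b)
    ia = ib = 0
    if not na and not nb:
        return out, mat
    x = min(a[0][0] if na else b[0][0], b[0][0] if nb else a[0][0])
    while ia < na or ib < nb:
        mask = 0
        nxt = None
        if ia < na:
            l, r, m = a[ia]
            if x < l:
                nxt = l
            else:
                mask |= m
                nxt = r
        if ib < nb:
            l, r, m = b[ib]
            cand = l if x < l else r
            if x >= l:
                mask |= m
            if nxt is None or cand < nxt:
                nxt = cand
        if mask != 0 and mask != full_mask:
            if out and out[-1][1] == x and out[-1][2] == mask:
                out[-1][1] = nxt
            else:
                out.append([x, nxt, mask])
            mat += nxt - x
        if ia < na and a[ia][1] <= nxt:
            ia += 1
        if ib < nb and b[ib][1] <= nxt:
            ib += 1
        x = nxt
    return out, mat


def _split_segments(segs, breakpoint):
    left, right = [], []
    for l, r, m in segs:
        if r <= breakpoint:
            left.append([l, r, m])
        elif l >= breakpoint:
            right.append([l, r, m])
        else:
            left.append([l, breakpoint, m])
            right.append([breakpoint, r, m])
    return left, right


class _State:
    """Lineage population with per-background indexes and cached rate sums."""

    def __init__(self, n, n_derived, L, p_sel, recomb_map):
        self.recomb_map = recomb_map
        self.p_sel = p_sel
        self.full_mask = (1 << n) - 1
        self.lineages: dict[int, _Lineage] = {}
        self.by_bg: dict[int, list[int]] = {0: [], 1: []}
        self.pos: dict[int, int] = {}  # idx -> position within its bg list
        self.next_id = 0
        self.total_mat = 0.0
        self.total_span = 0.0
        for i in range(n):
            self.add([[0.0, L, 1 << i]], 1 if i < n_derived else 0)

    def k(self, bg):
        return len(self.by_bg[bg])

    def add(self, segs, bg, mat=None):
        lin = _Lineage(segs, bg, self.recomb_map, mat)
        idx = self.next_id
        self.next_id += 1
        self.lineages[idx] = lin
        self.pos[idx] = len(self.by_bg[bg])
        self.by_bg[bg].append(idx)
        self.total_mat += lin.mat
        self.total_span += lin.span_rate
        return idx

    def drop(self, idx):
        lin = self.lineages.pop(idx)
        self.total_mat -= lin.mat
        self.total_span -= lin.span_rate
        lst = self.by_bg[lin.bg]
        j = self.pos.pop(idx)
        last = lst.pop()
        if last != idx:
            lst[j] = last
            self.pos[last] = j
        if not self.lineages:  # clear accumulated float residue at the end
            self.total_mat = 0.0
            self.total_span = 0.0

    def coalesce(self, rng, bg):
        lst = self.by_bg[bg]
        k = len(lst)
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        ia, ib = lst[i], lst[j]
        merged, mat = _merge_segments(
            self.lineages[ia].segs, self.lineages[ib].segs, self.full_mask
        )
        self.drop(ia)
        self.drop(ib)
        if merged:
            self.add(merged, bg, mat)

    def recombine(self, rng, x):
        """Split a lineage (chosen by map span) at a map-uniform breakpoint;
        the piece on the far side of the selected site re-samples its
        background from the current frequency x."""
        u = rng.random() * self.total_span
        acc = 0.0
        idx = None
        for i in self.by_bg[1]:
            acc += self.lineages[i].span_rate
            if u <= acc:
                idx = i
                break
        if idx is None:
            for i in self.by_bg[0]:
                acc += self.lineages[i].span_rate
                if u <= acc:
                    idx = i
                    break
        if idx is None:
            return
        lin = self.lineages[idx]
        bp = self.recomb_map.sample_breakpoint(
            lin.segs[0][0], lin.segs[-1][1], rng.random()
        )
        left, right = _split_segments(lin.segs, bp)
        if not left or not right:
            return
        bg = lin.bg
        self.drop(idx)
        new_bg = 1 if rng.random() < x else 0
        if bp > self.p_sel:  # selected site is on the left piece
            self.add(left, bg)
            self.add(right, new_bg)
        else:
            self.add(left, new_bg)
            self.add(right, bg)

    def mutate(self, rng, mutations):
        """Drop one mutation uniformly on the pooled ancestral material."""
        if not self.lineages:
            return
        u = rng.random() * self.total_mat
        acc = 0.0
        chosen = None
        for idx in self.by_bg[1]:
            lin = self.lineages[idx]
            acc += lin.mat
            if u <= acc:
                chosen = lin
                break
        if chosen is None:
            for idx in self.by_bg[0]:
                lin = self.lineages[idx]
                acc += lin.mat
                if u <= acc:
                    chosen = lin
                    break
        if chosen is None:  # float rounding put u past the last lineage
            chosen = self.lineages[next(reversed(self.lineages))]
            acc = u + chosen.mat
        # uniform within the chosen lineage's material
        v = chosen.mat - (acc - u)
        run = 0.0
        for l, r, m in chosen.segs:
            run += r - l
            if v <= run:
                mutations.append((r - (run - v), m))
                return
        l, r, m = chosen.segs[-1]
        mutations.append((r - 1e-12 * (r - l), m))


def _masks_to_matrix(masks, n):
    nbytes = (n + 7) // 8
    raw = np.frombuffer(
        b"".join(int(m).to_bytes(nbytes, "little") for m in masks), dtype=np.uint8
    ).reshape(len(masks), nbytes)
    bits = np.unpackbits(raw, axis=1, bitorder="little")[:, :n]
    return np.ascontiguousarray(bits.T)


def simulate_sweep_replicate(
    rng: np.random.Generator,
    *,
    n: int,
    n_derived: int,
    N: float,
    s: float,
    f: float,
    theta: float,
    recomb_map: RecombinationMap,
    L: float,
    p_sel: float,
    stochastic_trajectory: bool = True,
) -> tuple[np.ndarray, np.ndarray, int]:
    """One sweep replicate.

    Returns ``(positions, alleles, selected_index)`` where ``alleles`` is the
    n × S 0/1 matrix (rows 0..n_derived-1 carry the selected allele; callers
    may shuffle rows) and ``selected_index`` is the column of the selected
    site, placed at position ``p_sel``.
    """
    mu_bp = theta / (4.0 * N) / L
    traj, dt = sweep_trajectory(rng, f, s, N, stochastic=stochastic_trajectory)
    state = _State(n, n_derived, L, p_sel, recomb_map)
    mutations: list[tuple[float, int]] = []

    # sweep phase: walk the trajectory backwards in steps of dt generations
    for x in traj:
        t_in_step = 0.0
        while True:
            kd, ka = state.k(1), state.k(0)
            rate_cd = kd * (kd - 1) / 2.0 / (2.0 * N * x)
            rate_ca = ka * (ka - 1) / 2.0 / (2.0 * N * max(1.0 - x, 0.5 / N))
            rate_re = state.total_span
            rate_mu = mu_bp * state.total_mat
            total = rate_cd + rate_ca + rate_re + rate_mu
            if total <= 0:
                break
            tau = rng.exponential(1.0 / total)
            if t_in_step + tau >= dt:
                break
            t_in_step += tau
            u = rng.random() * total
            if u < rate_cd:
                state.coalesce(rng, 1)
            elif u < rate_cd + rate_ca:
                state.coalesce(rng, 0)
            elif u < rate_cd + rate_ca + rate_re:
                state.recombine(rng, x)
            else:
                state.mutate(rng, mutations)
        if not state.lineages:
            break

    # origin: remaining derived lineages merge into the founding chromosome
    derived = list(state.by_bg[1])
    if derived:
        segs = state.lineages[derived[0]].segs
        for idx in derived[1:]:
            segs, _ = _merge_segments(segs, state.lineages[idx].segs, state.full_mask)
        for idx in derived:
            state.drop(idx)
        if segs:
            state.add(segs, 0)

    # neutral phase: standard coalescent with recombination until full MRCA
    while state.lineages:
        k = state.k(0)
        rate_c = k * (k - 1) / 2.0 / (2.0 * N)
        rate_re = state.total_span
        rate_mu = mu_bp * state.total_mat
        total = rate_c + rate_re + rate_mu
        if total <= 0:  # pragma: no cover
            break
        u = rng.random() * total
        if u < rate_c:
            state.coalesce(rng, 0)
        elif u < rate_c + rate_re:
            state.recombine(rng, 0.0)
        else:
            state.mutate(rng, mutations)

    mutations.append((p_sel, (1 << n_derived) - 1))
    mutations.sort(key=lambda t: t[0])
    positions, masks = [], []
    last = -1.0
    for pos, mask in mutations:
        if pos <= last:  # duplicate-position guard
            pos = last + 1e-9
        positions.append(pos)
        masks.append(mask)
        last = pos
    positions = np.asarray(positions)
    # locate the selected site (its position may have been nudged by at most
    # a few duplicate-guard steps) by position + carrier-mask match
    cand = np.flatnonzero(np.isclose(positions, p_sel, atol=1e-6))
    sel_mask = (1 << n_derived) - 1
    sel_index = next(int(i) for i in cand if masks[i] == sel_mask)
    return positions, _masks_to_matrix(masks, n), sel_index
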