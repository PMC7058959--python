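"""Structured coalescent conditioned on a sweep trajectory, for any ploidy.

Backward-in-time ancestry simulation for the two-population design: an
equilibrium ancestral population splits in two; at the split a beneficial
mutation arises in the middle of an L bp locus in one population and sweeps
to fixation; n individuals (n*k haplotypes) are sampled per population at,
or ``tau_post`` generations after, fixation.

Ploidy k enters as the number of genome copies: a population of N
individuals holds N*k chromosomes, so the pairwise coalescence rate is
1/(N*k) per generation and the population-scaled rates are theta = 2*N*k*mu
and rho = 2*N*k*r.  During the sweep phase (run generation-by-generation
against the recorded trajectory) lineages in the selected population carry
an allelic class at the selected site: with derived frequency x, pairs
coalesce at 1/(x*N*k) within the derived class and 1/((1-x)*N*k) within the
ancestral class, and a recombination event separating a lineage's material
from the selected site redraws its class (derived with probability x).

The genealogy is recorded as tskit node/edge tables; mutations are dropped
afterwards under the infinite-sites model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import tskit

from .haplotypes import HaplotypeMatrix, read_ms, write_ms  # noqa: F401 (re-export)
from .trajectory import Trajectory

__all__ = [
    "LocusConfig",
    "Demography",
    "HaplotypeMatrix",
    "simulate_sweep_ancestry",
    "simulate_sweep_sample",
    "simulate_neutral_ancestry",
    "simulate_neutral_sample",
    "drop_mutations",
    "write_ms",
    "read_ms",
]

DERIVED = 1
ANCESTRAL = 0


@dataclass(frozen=True)
class LocusConfig:
    """Locus geometry and per-generation rates.

    L : locus length in bp.
    sel_pos : selected-site position in bp (default L/2).
    mu : per-site per-generation mutation rate.
    r : per-adjacent-bp per-generation recombination rate.
    """

    L: float = 1_000_000.0
    sel_pos: float | None = None
    mu: float = 1e-8
    r: float = 1e-8

    def __post_init__(self) -> None:
        if self.sel_pos is None:
            object.__setattr__(self, "sel_pos", self.L / 2)
        if not 0 <= self.sel_pos <= self.L:
            raise ValueError("sel_pos must lie within [0, L]")
        if self.mu < 0 or self.r < 0:
            raise ValueError("mu and r must be non-negative")


@dataclass(frozen=True)
class Demography:
    """Sampling design: N individuals per population, k genome copies each.

    sample_mode "individuals" samples n individuals (n*k haplotypes) per
    population; "alleles" samples a fixed total of n haplotypes per
    population regardless of ploidy (equal-allele comparison).
    """

    N: int
    k_genomic: int = 2
    n: int = 10
    tau_post: float = 0.0
    sample_mode: str = "individuals"

    def __post_init__(self) -> None:
        if self.sample_mode not in ("individuals", "alleles"):
            raise ValueError("sample_mode must be 'individuals' or 'alleles'")
        if self.tau_post < 0:
            raise ValueError("tau_post must be >= 0")
        if self.n_haplotypes > self.N * self.k_genomic:
            raise ValueError("cannot sample more haplotypes than genome copies")

    @property
    def n_haplotypes(self) -> int:
        """Haplotypes sampled per population."""
        if self.sample_mode == "individuals":
            return self.n * self.k_genomic
        return self.n


class _Lineage:
    """An ancestral lineage: sorted list of [left, right, node, ndesc] segments."""

    __slots__ = ("segments", "pop", "cls")

    def __init__(self, segments, pop, cls=None):
        self.segments = segments
        self.pop = pop
        self.cls = cls

    def hull(self, sel_pos: float | None = None) -> tuple[float, float]:
        lo = self.segments[0][0]
        hi = self.segments[-1][1]
        if sel_pos is not None:
            lo = min(lo, sel_pos)
            hi = max(hi, sel_pos)
        return lo, hi

    def hull_len(self, sel_pos: float | None = None) -> float:
        lo, hi = self.hull(sel_pos)
        return hi - lo


class _AncestrySim:
    """Hudson-style ancestral recombination graph recorder on tskit tables."""

    def __init__(self, demog: Demography, locus: LocusConfig, rng: np.random.Generator,
                 n_pops: int = 2):
        self.demog = demog
        self.locus = locus
        self.rng = rng
        self.Nk = demog.N * demog.k_genomic  # genome copies per population
        self.tables = tskit.TableCollection(sequence_length=locus.L)
        for _ in range(max(n_pops, 1)):
            self.tables.populations.add_row()
        nh = demog.n_haplotypes
        self.lineages: list[_Lineage] = []
        for pop in range(n_pops):
            for _ in range(nh):
                node = self.tables.nodes.add_row(
                    flags=tskit.NODE_IS_SAMPLE, time=0.0, population=pop
                )
                self.lineages.append(_Lineage([[0.0, locus.L, node, 1]], pop))
        self.n_total = nh * n_pops
        self.time = 0.0

    # -- structural events -------------------------------------------------

    def _merge(self, a: _Lineage, b: _Lineage, time: float) -> None:
        """Coalesce two lineages at `time`; record edges; drop MRCA material."""
        sa, sb = a.segments, b.segments
        pts = sorted({s[0] for s in sa} | {s[1] for s in sa}
                     | {s[0] for s in sb} | {s[1] for s in sb})
        out: list[list] = []
        new_node = -1
        edges = self.tables.edges
        ia = ib = 0
        for left, right in zip(pts, pts[1:]):
            while ia < len(sa) and sa[ia][1] <= left:
                ia += 1
            while ib < len(sb) and sb[ib][1] <= left:
                ib += 1
            seg_a = sa[ia] if ia < len(sa) and sa[ia][0] <= left else None
            seg_b = sb[ib] if ib < len(sb) and sb[ib][0] <= left else None
            if seg_a is not None and seg_b is not None:
                if new_node < 0:
                    new_node = self.tables.nodes.add_row(
                        time=time, population=a.pop
                    )
                edges.add_row(left, right, new_node, seg_a[2])
                edges.add_row(left, right, new_node, seg_b[2])
                nd = seg_a[3] + seg_b[3]
                if nd < self.n_total:
                    out.append([left, right, new_node, nd])
            elif seg_a is not None:
                out.append([left, right, seg_a[2], seg_a[3]])
            elif seg_b is not None:
                out.append([left, right, seg_b[2], seg_b[3]])
        # compact adjacent pieces of the same node carrying the same subtree
        comp: list[list] = []
        for seg in out:
            if comp and comp[-1][2] == seg[2] and comp[-1][3] == seg[3] \
                    and comp[-1][1] == seg[0]:
                comp[-1][1] = seg[1]
            else:
                comp.append(seg)
        self.lineages.remove(a)
        self.lineages.remove(b)
        if comp:
            self.lineages.append(_Lineage(comp, a.pop, a.cls))

    def _split(self, lin: _Lineage, pos: float, sweep_x: float | None) -> None:
        """Recombination at `pos` on lineage `lin`.

        During the sweep phase (`sweep_x` is the current derived frequency in
        the selected population) the piece on the far side of the selected
        site from `pos` redraws its allelic class: derived with probability
        sweep_x.  Pieces without ancestral material are discarded.
        """
        left_segs: list[list] = []
        right_segs: list[list] = []
        for l, r, node, nd in lin.segments:
            if r <= pos:
                left_segs.append([l, r, node, nd])
            elif l >= pos:
                right_segs.append([l, r, node, nd])
            else:
                left_segs.append([l, pos, node, nd])
                right_segs.append([pos, r, node, nd])
        if not left_segs or not right_segs:
            # breakpoint between the material and the selected site: the
            # material moves onto a chromosome with a freshly drawn class
            if sweep_x is not None:
                lin.cls = DERIVED if self.rng.random() < sweep_x else ANCESTRAL
            return
        self.lineages.remove(lin)
        keep_cls = lin.cls
        new_cls = lin.cls
        if sweep_x is not None:
            new_cls = DERIVED if self.rng.random() < sweep_x else ANCESTRAL
        sel = self.locus.sel_pos
        if sel is not None and pos > sel:
            # left piece carries the selected site
            self.lineages.append(_Lineage(left_segs, lin.pop, keep_cls))
            self.lineages.append(_Lineage(right_segs, lin.pop, new_cls))
        else:
            self.lineages.append(_Lineage(left_segs, lin.pop, new_cls))
            self.lineages.append(_Lineage(right_segs, lin.pop, keep_cls))

    # -- neutral (continuous-time) phases ----------------------------------

    def run_neutral(self, t_end: float) -> None:
        """Exponential-waiting-time coalescent/recombination until `t_end`.

        Lineages coalesce only within their population label, at pair rate
        1/(N*k) per generation; each lineage recombines at rate r times its
        ancestral-material hull length.
        """
        r = self.locus.r
        rng = self.rng
        while self.lineages:
            pops: dict[int, list[_Lineage]] = {}
            for lin in self.lineages:
                pops.setdefault(lin.pop, []).append(lin)
            coal_rates = {
                p: len(group) * (len(group) - 1) / 2 / self.Nk
                for p, group in pops.items()
            }
            hulls = [lin.hull_len() for lin in self.lineages]
            rec_rate = r * sum(hulls)
            total = sum(coal_rates.values()) + rec_rate
            if total <= 0:
                self.time = max(self.time, t_end if math.isfinite(t_end) else self.time)
                return
            wait = rng.exponential(1.0 / total)
            if self.time + wait >= t_end:
                self.time = t_end
                return
            self.time += wait
            u = rng.random() * total
            if u < rec_rate:
                # pick lineage weighted by hull length
                target = u / r
                acc = 0.0
                for lin, hl in zip(list(self.lineages), hulls):
                    acc += hl
                    if target <= acc:
                        lo, hi = lin.hull()
                        self._split(lin, rng.uniform(lo, hi), None)
                        break
            else:
                u -= rec_rate
                for p, rate in coal_rates.items():
                    if u < rate:
                        group = pops[p]
                        i, j = rng.choice(len(group), size=2, replace=False)
                        self._merge(group[i], group[j], self.time)
                        break
                    u -= rate

    # -- sweep (discrete-generation) phase ---------------------------------

    def run_sweep(self, traj: Trajectory, selected_pop: int = 0) -> None:
        """Generation-by-generation structured phase against the trajectory.

        Walks backward from fixation: backward step j uses the parent
        generation's derived frequency x = p[T-1-j].  At the trajectory
        origin the remaining derived lineages are forcibly coalesced and the
        survivor joins the ancestral class.
        """
        if not traj.fixed:
            raise ValueError("sweep simulation requires a fixation-conditioned trajectory")
        freqs = traj.freqs
        T = len(freqs) - 1
        rng = self.rng
        r = self.locus.r
        sel = self.locus.sel_pos
        for lin in self.lineages:
            if lin.pop == selected_pop:
                lin.cls = DERIVED
        t0 = self.time
        for j in range(T):
            x = float(freqs[T - 1 - j])
            if x <= 0 and any(
                lin.pop == selected_pop and lin.cls == DERIVED for lin in self.lineages
            ):
                raise RuntimeError("derived lineages remain but trajectory frequency is 0")
            base = t0 + j
            ev = [0]

            def next_time():
                ev[0] += 1
                return base + ev[0] * 1e-4

            # recombination events this generation (start-of-generation rates)
            sel_lin = [l for l in self.lineages if l.pop == selected_pop]
            other = [l for l in self.lineages if l.pop != selected_pop]
            hulls = [l.hull_len(sel) for l in sel_lin] + [l.hull_len() for l in other]
            lin_order = sel_lin + other
            tot_hull = sum(hulls)
            n_rec = rng.poisson(r * tot_hull) if tot_hull > 0 else 0
            for _ in range(n_rec):
                w = np.asarray(hulls)
                idx = rng.choice(len(lin_order), p=w / w.sum())
                lin = lin_order[idx]
                if lin not in self.lineages:
                    continue  # removed by an earlier split this generation
                if lin.pop == selected_pop:
                    lo, hi = lin.hull(sel)
                    self._split(lin, rng.uniform(lo, hi), x)
                else:
                    lo, hi = lin.hull()
                    self._split(lin, rng.uniform(lo, hi), None)
            # coalescence within each class / population
            self._gen_coalesce(
                [l for l in self.lineages if l.pop == selected_pop and l.cls == DERIVED],
                x * self.Nk, next_time,
            )
            self._gen_coalesce(
                [l for l in self.lineages
                 if l.pop == selected_pop and l.cls == ANCESTRAL],
                (1.0 - x) * self.Nk, next_time,
            )
            self._gen_coalesce(
                [l for l in self.lineages if l.pop != selected_pop],
                self.Nk, next_time,
            )
        # trajectory origin: single derived copy left in the population
        base = t0 + T
        ev = 0
        derived = [l for l in self.lineages
                   if l.pop == selected_pop and l.cls == DERIVED]
        while len(derived) > 1:
            ev += 1
            i, j = self.rng.choice(len(derived), size=2, replace=False)
            self._merge(derived[i], derived[j], base + ev * 1e-4)
            derived = [l for l in self.lineages
                       if l.pop == selected_pop and l.cls == DERIVED]
        for lin in self.lineages:
            lin.cls = None
        self.time = base + (ev + 1) * 1e-4

    def _gen_coalesce(self, group: list[_Lineage], copies: float, next_time) -> None:
        """Within-generation mergers for one allelic class holding `copies` parents.

        Forces the lineage count down to ceil(copies) first (cannot exceed the
        number of parental chromosomes), then applies probabilistic mergers at
        pair probability 1/copies, allowing multiple per generation.
        """
        rng = self.rng
        if copies <= 0:
            copies = 1.0
        cap = max(1, math.ceil(copies))
        group = [l for l in group if l in self.lineages]
        while len(group) > cap:
            i, j = rng.choice(len(group), size=2, replace=False)
            self._merge(group[i], group[j], next_time())
            group = [l for l in group if l in self.lineages]
        while len(group) >= 2:
            m = len(group)
            pr = m * (m - 1) / 2.0 / copies
            if pr < 1.0 and rng.random() >= pr:
                break
            i, j = rng.choice(m, size=2, replace=False)
            self._merge(group[i], group[j], next_time())
            group = [l for l in group if l in self.lineages]

    def merge_populations(self) -> None:
        for lin in self.lineages:
            lin.pop = 0

    def finish(self) -> tskit.TreeSequence:
        self.run_neutral(math.inf)
        self.tables.sort()
        self.tables.edges.squash()
        self.tables.sort()
        return self.tables.tree_sequence()


# ---------------------------------------------------------------------------
# public drivers


def simulate_sweep_ancestry(
    traj: Trajectory,
    demog: Demography,
    locus: LocusConfig,
    rng: np.random.Generator,
) -> tskit.TreeSequence:
    """Genealogy of a two-population sample conditioned on a sweep.

    Population 0 experienced the sweep; population 1 is the neutral control.
    Backward in time: ``tau_post`` generations of neutral drift, the sweep
    phase dictated by the (reversed) trajectory, then a single merged
    ancestral population run to the grand MRCA.  The trajectory may have
    been generated at a different ploidy than ``demog.k_genomic`` (the
    trajectory-versus-diversity decomposition).
    """
    sim = _AncestrySim(demog, locus, rng, n_pops=2)
    if demog.tau_post > 0:
        sim.run_neutral(demog.tau_post)
    sim.run_sweep(traj, selected_pop=0)
    sim.merge_populations()
    return sim.finish()


def simulate_neutral_ancestry(
    demog: Demography,
    locus: LocusConfig,
    split_gens: float,
    rng: np.random.Generator,
    n_pops: int = 2,
) -> tskit.TreeSequence:
    """Neutral genealogy: `n_pops` populations merging `split_gens` ago."""
    if split_gens < 0:
        raise ValueError("split_gens must be >= 0")
    sim = _AncestrySim(demog, locus, rng, n_pops=n_pops)
    if split_gens > 0 and n_pops > 1:
        sim.run_neutral(split_gens)
    sim.merge_populations()
    return sim.finish()


def drop_mutations(
    ts: tskit.TreeSequence,
    locus: LocusConfig,
    rng: np.random.Generator,
    pop_sizes: tuple[int, ...],
    k: int,
) -> HaplotypeMatrix:
    """Infinite-sites mutations on a recorded genealogy.

    Per marginal tree of span ell and total branch length B (generations),
    the mutation count is Poisson(mu * ell * B); each mutation lands on a
    branch chosen proportionally to its length and at a uniform position,
    and flips the leaves beneath it to the derived state.  Positions are
    reported at the 1e-6-of-L resolution of the ms dialect and kept unique.
    """
    n = ts.num_samples
    cols: list[np.ndarray] = []
    pos: list[float] = []
    for tree in ts.trees():
        left, right = tree.interval
        B = tree.total_branch_length
        lam = locus.mu * (right - left) * B
        if lam <= 0:
            continue
        n_mut = rng.poisson(lam)
        if n_mut == 0:
            continue
        nodes = [u for u in tree.nodes() if tree.parent(u) != tskit.NULL]
        blens = np.array([tree.branch_length(u) for u in nodes])
        probs = blens / blens.sum()
        picks = rng.choice(len(nodes), size=n_mut, p=probs)
        for u_idx in picks:
            col = np.zeros(n, dtype=np.uint8)
            for leaf in tree.samples(nodes[u_idx]):
                col[leaf] = 1
            cols.append(col)
            pos.append(rng.uniform(left, right))
    if not cols:
        return HaplotypeMatrix(
            np.zeros((n, 0), dtype=np.uint8), np.empty(0), tuple(pop_sizes),
            k=k, L=locus.L,
        )
    order = np.argsort(pos)
    fr = np.round(np.asarray(pos)[order] / locus.L, 6)
    for i in range(1, len(fr)):  # enforce strictly increasing at dialect resolution
        if fr[i] <= fr[i - 1]:
            fr[i] = fr[i - 1] + 1e-6
    data = np.column_stack([cols[i] for i in order])
    return HaplotypeMatrix(data, fr * locus.L, tuple(pop_sizes), k=k, L=locus.L)


def simulate_sweep_sample(
    traj: Trajectory,
    demog: Demography,
    locus: LocusConfig,
    rng: np.random.Generator,
) -> HaplotypeMatrix:
    """Sweep genealogy plus mutations: the full two-population haplotype sample."""
    ts = simulate_sweep_ancestry(traj, demog, locus, rng)
    nh = demog.n_haplotypes
    return drop_mutations(ts, locus, rng, (nh, nh), demog.k_genomic)


def simulate_neutral_sample(
    demog: Demography,
    locus: LocusConfig,
    split_gens: float,
    rng: np.random.Generator,
    n_pops: int = 2,
) -> HaplotypeMatrix:
    """Neutral control sample with the same demography and no sweep phase."""
    ts = simulate_neutral_ancestry(demog, locus, split_gens, rng, n_pops=n_pops)
    nh = demog.n_haplotypes
    return drop_mutations(ts, locus, rng, tuple([nh] * n_pops), demog.k_genomic)
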