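"""Structured-coalescent simulator and synthetic cohort generator.

Backwards-in-time coalescent with demes, continuous migration,
piecewise-constant sizes, and population merges (splits, viewed
forwards), plus infinite-sites mutation. Two output modes share one
event loop:

* branch mode — full genealogies (branch lengths + descendant leaf
  sets) for dropping mutations and building genotype cohorts;
* count mode — per-branch descendant-count accumulation into an
  unfolded joint SFS (branch-length expectation), the low-variance
  input to demographic likelihoods.

Units follow the diffusion-ecosystem convention: population sizes are
relative to a reference size ``N_ref``, times are in units of
``2 N_ref`` generations (backwards from sampling), migration rates are
scaled ``M = 2 N_ref m``, and ``theta = 4 N_ref mu`` per site. A branch
of scaled length ``l`` spanning ``L`` bp receives
``Poisson(l * theta/2 * L)`` mutations.

The cohort generator emulates the study design this package targets: a
multi-scaffold diploid genome for 2 wild + 7 domestic duck populations
(78 individuals), a domestication bottleneck, designated sweep windows
(local coalescent-size reduction in the domestic demes), and injected
phenotype-diagnostic loci, with synthesized QC annotations so the
hard-filter stage is exercisable. Genealogies are independent between
windows; sites within a window are fully linked (no recombination).
"""

from __future__ import annotations

import json
import logging
import math
import random
from dataclasses import dataclass, field, asdict
from itertools import accumulate

import numpy as np
import pandas as pd

from .variant_io import VariantTable, PopulationMap, QC_FIELDS, SITE_COLUMNS

logger = logging.getLogger("anaspop")

_INF = float("inf")
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# compiled demography (plain arrays; produced by DemographicModel.compile())
# ---------------------------------------------------------------------------

@dataclass
class CompiledDemography:
    """Event-list form of a demographic model, ready for simulation.

    events: time-sorted tuples ``("size", t, pop, size)`` or
    ``("merge", t, src, dst, dst_size_or_None)`` with pops as indices
    into ``pop_names``. ``migration[i, j]`` is the backwards rate at
    which a lineage in ``i`` hops to ``j`` (equals the scaled forward
    rate of migration into ``i`` from ``j``).
    """

    pop_names: list
    initial_sizes: np.ndarray
    active0: np.ndarray
    migration: np.ndarray
    events: list

    def scaled_sizes(self, pops, factor: float) -> "CompiledDemography":
        """Return a copy with the sizes of ``pops`` (names) divided by ``factor``."""
        idx = {self.pop_names.index(p) for p in pops}
        sizes = self.initial_sizes.copy()
        for i in idx:
            if np.isfinite(sizes[i]):
                sizes[i] /= factor
        events = []
        for ev in self.events:
            if ev[0] == "size" and ev[2] in idx:
                events.append(("size", ev[1], ev[2], ev[3] / factor))
            elif ev[0] == "merge" and ev[3] in idx and ev[4] is not None:
                events.append(("merge", ev[1], ev[2], ev[3], ev[4] / factor))
            else:
                events.append(ev)
        return CompiledDemography(self.pop_names, sizes, self.active0.copy(),
                                  self.migration, events)


def _compiled(demog) -> CompiledDemography:
    return demog.compile() if hasattr(demog, "compile") else demog


# ---------------------------------------------------------------------------
# core event loop
# ---------------------------------------------------------------------------

def _run_coalescent(cd: CompiledDemography, init, rng: random.Random,
                    out=None, branches=None, stats=None,
                    additive_vals: bool = False) -> float:
    """Run one structured-coalescent sample path.

    ``init`` is a list of (pop_index, value) leaves, where value is a
    flat SFS index (count mode, ``out`` list) or a leaf bitmask (branch
    mode, ``branches`` list). Returns the TMRCA in scaled time.

    When ``stats`` is a dict it is filled with the path statistics that
    importance reweighting needs: per-population integrated pairwise
    coalescent intensity ``A`` and lineage-time ``K`` (= integral of the
    lineage count), coalescence counts ``ncoal``, and migration hop
    counts ``hops[p][q]``.
    """
    npop = len(cd.pop_names)
    sizes = cd.initial_sizes.astype(float).copy()
    active = cd.active0.copy()
    mig = cd.migration

    lin_pop, lin_birth, lin_val = [], [], []
    bypop = [[] for _ in range(npop)]
    for p, val in init:
        lid = len(lin_pop)
        lin_pop.append(p)
        lin_birth.append(0.0)
        lin_val.append(val)
        bypop[p].append(lid)
    n_lineages = len(lin_pop)
    count_mode = out is not None
    additive = count_mode or additive_vals

    def migsums():
        ms = [sum(mig[p, q] for q in range(npop) if active[q] and q != p)
              if active[p] else 0.0 for p in range(npop)]
        ch = [(p, q) for p in range(npop) if active[p]
              for q in range(npop) if q != p and active[q] and mig[p, q] > 0.0]
        return ms, ch

    msum, channels = migsums()
    events = cd.events
    ei, n_events = 0, len(events)
    t = 0.0
    expovariate, uniform, randrange = rng.expovariate, rng.random, rng.randrange
    if stats is not None:
        stats["A"] = [0.0] * npop
        stats["K"] = [0.0] * npop
        stats["Kmig"] = {}
        stats["ncoal"] = [0] * npop
        stats["hops"] = [[0] * npop for _ in range(npop)]

    while n_lineages > 1:
        total = 0.0
        coal = [0.0] * npop
        migr = [0.0] * npop
        for p in range(npop):
            k = len(bypop[p])
            if k == 0:
                continue
            if k > 1:
                c = k * (k - 1) * 0.5 / sizes[p]
                coal[p] = c
                total += c
            if msum[p] > 0.0:
                m = k * msum[p]
                migr[p] = m
                total += m
        t_ev = events[ei][1] if ei < n_events else _INF
        if total <= 0.0:
            if t_ev == _INF:
                raise RuntimeError("remaining lineages can never coalesce "
                                   "(model does not merge all populations)")
            if stats is not None:
                _accumulate(stats, bypop, coal, t_ev - t, npop, channels)
            t = t_ev
        else:
            dt = expovariate(total)
            if t + dt >= t_ev:
                if stats is not None:
                    _accumulate(stats, bypop, coal, t_ev - t, npop, channels)
                t = t_ev
            else:
                if stats is not None:
                    _accumulate(stats, bypop, coal, dt, npop, channels)
                t += dt
                u = uniform() * total
                for p in range(npop):
                    if coal[p] and u < coal[p]:
                        lst = bypop[p]
                        k = len(lst)
                        i = randrange(k)
                        a = lst[i]; lst[i] = lst[-1]; lst.pop()
                        i = randrange(k - 1)
                        b = lst[i]; lst[i] = lst[-1]; lst.pop()
                        if count_mode:
                            out[lin_val[a]] += t - lin_birth[a]
                            out[lin_val[b]] += t - lin_birth[b]
                        else:
                            branches.append((t - lin_birth[a], lin_val[a]))
                            branches.append((t - lin_birth[b], lin_val[b]))
                        newval = (lin_val[a] + lin_val[b]) if additive \
                            else (lin_val[a] | lin_val[b])
                        lid = len(lin_pop)
                        lin_pop.append(p)
                        lin_birth.append(t)
                        lin_val.append(newval)
                        lst.append(lid)
                        n_lineages -= 1
                        if stats is not None:
                            stats["ncoal"][p] += 1
                        break
                    u -= coal[p]
                    if migr[p] and u < migr[p]:
                        u2 = uniform() * msum[p]
                        dest = -1
                        for q in range(npop):
                            if q == p or not active[q]:
                                continue
                            u2 -= mig[p, q]
                            if u2 < 0.0:
                                dest = q
                                break
                        if dest < 0:  # numerical edge
                            dest = next(q for q in range(npop)
                                        if q != p and active[q] and mig[p, q] > 0)
                        lst = bypop[p]
                        i = randrange(len(lst))
                        lid = lst[i]; lst[i] = lst[-1]; lst.pop()
                        bypop[dest].append(lid)
                        lin_pop[lid] = dest
                        if stats is not None:
                            stats["hops"][p][dest] += 1
                        break
                    u -= migr[p]
                continue
        # demographic event at t == t_ev
        ev = events[ei]
        ei += 1
        if ev[0] == "size":
            _, _, pop, size = ev
            sizes[pop] = size
            active[pop] = True
        else:
            _, _, src, dst, dsize = ev
            if dsize is not None:
                sizes[dst] = dsize
            if not active[dst]:
                if not np.isfinite(sizes[dst]):
                    raise RuntimeError(f"merge destination {cd.pop_names[dst]} has no size")
                active[dst] = True
            for lid in bypop[src]:
                lin_pop[lid] = dst
            bypop[dst].extend(bypop[src])
            bypop[src] = []
            active[src] = False
        msum, channels = migsums()
    return t


def _accumulate(stats, bypop, coal, adv, npop, channels):
    if adv <= 0.0:
        return
    A, K = stats["A"], stats["K"]
    for p in range(npop):
        k = len(bypop[p])
        if k:
            K[p] += k * adv
            if coal[p]:
                A[p] += coal[p] * adv
    if channels:
        kmig = stats["Kmig"]
        for ch in channels:
            k = len(bypop[ch[0]])
            if k:
                kmig[ch] = kmig.get(ch, 0.0) + k * adv


# ---------------------------------------------------------------------------
# public simulation operations
# ---------------------------------------------------------------------------

@dataclass
class Genealogy:
    """One realized genealogy: branches as (scaled length, leaf bitmask)."""

    branches: list
    leaf_pops: list
    tmrca: float

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_pops)

    @property
    def total_branch_length(self) -> float:
        return float(sum(b[0] for b in self.branches))


def simulate_genealogy(demog, sample_sizes: dict, rng) -> Genealogy:
    """Simulate one genealogy.

    ``sample_sizes`` maps sampled population name -> haplotype count;
    leaves are numbered consecutively in that order. ``rng`` is a
    ``random.Random`` (or an int seed).
    """
    cd = _compiled(demog)
    if isinstance(rng, int):
        rng = random.Random(rng)
    init, leaf_pops = [], []
    leaf = 0
    for name, count in sample_sizes.items():
        p = cd.pop_names.index(name)
        for _ in range(int(count)):
            init.append((p, 1 << leaf))
            leaf_pops.append(p)
            leaf += 1
    branches = []
    tmrca = _run_coalescent(cd, init, rng, branches=branches)
    return Genealogy(branches, leaf_pops, tmrca)


def branch_sfs(demog, sample_sizes: dict, n_reps: int, seed) -> np.ndarray:
    """Monte-Carlo expected unfolded joint branch-length SFS.

    Averages, over ``n_reps`` independent genealogies, the total branch
    length subtending each per-population descendant-count cell; the
    expected count SFS is this array times ``theta/2`` per site. Shape
    is ``(n1+1, ..., nk+1)`` over the populations in ``sample_sizes``
    order (corner cells stay zero).
    """
    cd = _compiled(demog)
    names = list(sample_sizes)
    dims = [int(sample_sizes[p]) + 1 for p in names]
    strides = [int(np.prod(dims[i + 1:])) for i in range(len(dims))]
    size = int(np.prod(dims))
    init = []
    for k, name in enumerate(names):
        p = cd.pop_names.index(name)
        init.extend((p, strides[k]) for _ in range(int(sample_sizes[name])))
    rng = random.Random(seed)
    out = [0.0] * size
    for _ in range(int(n_reps)):
        _run_coalescent(cd, init, rng, out=out)
    arr = np.array(out).reshape(dims) / float(n_reps)
    return arr


def branch_sfs_grid(demog, sample_sizes: dict, n_reps: int, seed,
                    logweight_fns) -> tuple:
    """Importance-reweighted expected branch SFS on a parameter grid.

    Simulates ``n_reps`` genealogies ONCE under the base model and, for
    each function in ``logweight_fns`` (mapping the per-replicate path
    statistics to a log likelihood-ratio versus the base model), returns
    the self-normalized weighted expected unfolded SFS. Because every
    grid point reuses the same genealogies, the resulting profile is a
    smooth function of the parameter — the key variance reduction for
    rate-scaling parameters (population sizes, migration rates), whose
    path likelihood ratio is exactly
    ``prod(rate'/rate over realized events) * exp(-(Lambda' - Lambda))``
    and is computable from the tracked integrals.

    Returns ``(array of shape (G, n1+1, ..., nk+1), effective sample
    sizes per grid point)``.
    """
    cd = _compiled(demog)
    names = list(sample_sizes)
    dims = [int(sample_sizes[p]) + 1 for p in names]
    strides = [int(np.prod(dims[i + 1:])) for i in range(len(dims))]
    size = int(np.prod(dims))
    init = []
    for k, name in enumerate(names):
        p = cd.pop_names.index(name)
        init.extend((p, strides[k]) for _ in range(int(sample_sizes[name])))
    rng = random.Random(seed)
    n_grid = len(logweight_fns)
    acc = np.zeros((n_grid, size))
    wsum = np.zeros(n_grid)
    ess_num = np.zeros(n_grid)
    for _ in range(int(n_reps)):
        branches = []
        stats = {}
        _run_coalescent(cd, init, rng, branches=branches, stats=stats,
                        additive_vals=True)
        logw = np.array([fn(stats) for fn in logweight_fns])
        w = np.exp(logw)
        wsum += w
        ess_num += w * w
        if branches:
            idx = np.fromiter((b[1] for b in branches), dtype=np.intp,
                              count=len(branches))
            lens = np.fromiter((b[0] for b in branches), dtype=float,
                               count=len(branches))
            np.add.at(acc, (slice(None), idx), w[:, None] * lens[None, :])
    ess = wsum ** 2 / np.where(ess_num > 0, ess_num, 1.0)
    out = acc / wsum[:, None]
    return out.reshape((n_grid, *dims)), ess


def drop_mutations(genealogy: Genealogy, theta_per_site: float, length: int, rng):
    """Infinite-sites mutations on a genealogy.

    Draws ``Poisson(total_branch_length * theta/2 * length)`` mutations,
    each at a distinct uniform 0-based position, assigned to a branch
    with probability proportional to branch length. Returns a
    position-sorted list of ``(pos0, derived_leaf_bitmask)``.
    """
    if theta_per_site < 0:
        raise ValueError("theta must be >= 0")
    if isinstance(rng, int):
        rng = random.Random(rng)
    total = genealogy.total_branch_length
    lam = total * 0.5 * theta_per_site * length
    n_mut = _poisson(lam, rng)
    n_mut = min(n_mut, length)  # infinite-sites positions must be distinct
    if n_mut == 0 or not genealogy.branches:
        return []
    positions = rng.sample(range(length), n_mut)
    cum = list(accumulate(b[0] for b in genealogy.branches))
    muts = []
    for pos in positions:
        u = rng.random() * total
        i = _bisect(cum, u)
        muts.append((pos, genealogy.branches[i][1]))
    muts.sort(key=lambda m: m[0])
    return muts


def _poisson(lam: float, rng: random.Random) -> int:
    if lam <= 0:
        return 0
    if lam > 50:  # normal approximation far in the bulk is fine for counts this large
        return max(0, int(round(rng.gauss(lam, math.sqrt(lam)))))
    # Knuth
    limit = math.exp(-lam)
    k, prod = 0, rng.random()
    while prod > limit:
        prod *= rng.random()
        k += 1
    return k


def _bisect(cum, u):
    lo, hi = 0, len(cum) - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if cum[mid] < u:
            lo = mid + 1
        else:
            hi = mid
    return lo


# ---------------------------------------------------------------------------
# cohort configuration (defaults are the emulated study conditions)
# ---------------------------------------------------------------------------

#: Nine duck populations with diploid sample sizes (two wild mallard
#: populations, three meat breeds, three egg breeds, one dual-purpose).
DEFAULT_POPULATIONS = {
    "MDN": 8, "MDZ": 14,            # wild mallards (Ningxia, Zhejiang)
    "PK": 8, "CV": 8, "ML": 8,      # meat breeds (Pekin, Cherry Valley, maple leaf)
    "JD": 8, "SM": 8, "SX": 8,      # egg breeds (Jin Ding, Shan Ma, Shao Xing)
    "GY": 8,                        # dual-purpose (Gao You)
}

#: population -> demographic deme of the three-population model.
DEFAULT_POP_DEME = {
    "MDN": "wild", "MDZ": "wild",
    "PK": "meat", "CV": "meat", "ML": "meat",
    "JD": "eggdp", "SM": "eggdp", "SX": "eggdp", "GY": "eggdp",
}

#: population -> group labels: production type, wild/domestic, plumage.
DEFAULT_POP_GROUPS = {
    "MDN": ("wild", "non_white"),
    "MDZ": ("wild", "non_white"),
    "PK": ("meat", "domestic", "white"),
    "CV": ("meat", "domestic", "white"),
    "ML": ("meat", "domestic", "white"),
    "JD": ("egg", "domestic", "non_white"),
    "SM": ("egg", "domestic", "non_white"),
    "SX": ("egg", "domestic", "non_white"),
    "GY": ("dual_purpose", "domestic", "non_white"),
}

#: demes whose coalescent sizes are shrunk inside sweep windows.
DOMESTIC_DEMES = ("meat", "eggdp", "dom_anc")


@dataclass
class SweepSpec:
    """A designated sweep region: domestic coalescent sizes / factor."""

    scaffold: str
    start: int
    end: int
    factor: float = 10.0

    def __post_init__(self):
        if self.factor < 1:
            raise ValueError("sweep reduction factor must be >= 1")


@dataclass
class DiagnosticSpec:
    """Variants fixed homozygous-alt in one group, absent elsewhere."""

    scaffold: str
    positions: list
    group: str = "white"
    var_classes: list | None = None  # per-position "SNP"/"INDEL"; default all SNP


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the resequencing design this package targets:
    78 diploids in nine populations mapped onto a three-deme
    single-domestication demography (mallard reference size
    ``n_ref = 100,000``; domestication bottleneck Ne 320), mutation
    rate 1.191e-9 per bp per generation, mean sequencing depth 6.42x,
    and a small INDEL fraction with 1-bp INDELs predominant.
    """

    seed: int
    populations: dict = field(default_factory=lambda: dict(DEFAULT_POPULATIONS))
    pop_deme: dict = field(default_factory=lambda: dict(DEFAULT_POP_DEME))
    pop_groups: dict = field(default_factory=lambda: dict(DEFAULT_POP_GROUPS))
    model: object = None            # DemographicModel; default single-domestication duck model
    n_scaffolds: int = 10
    scaffold_length: int = 50_000
    segment_bp: int = 10_000        # independent-genealogy segment length
    mu: float = 1.191e-9
    n_ref: float = 100_000.0
    missingness: float = 0.05
    indel_fraction: float = 0.079   # ~3.1M INDELs vs 36.1M SNPs
    indel_p1: float = 0.3863        # P(1-bp INDEL); geometric length law
    deletion_prob: float = 0.55     # deletions slightly outnumber insertions
    mean_depth: float = 6.42
    qc_fail_fraction: float = 0.0   # inject failing QC annotations for filter tests
    sweeps: list = field(default_factory=list)
    diagnostics: list = field(default_factory=list)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if any(v < 1 for v in self.populations.values()):
            raise ValueError("sample sizes must be >= 1")

    @property
    def theta_site(self) -> float:
        return 4.0 * self.n_ref * self.mu

    def resolved_model(self):
        if self.model is not None:
            return self.model
        from .demography import duck_model2  # deferred: demography imports this module
        return duck_model2(self.n_ref)

    def popmap(self) -> PopulationMap:
        sample_to_pop = {}
        for pop, n in self.populations.items():
            for i in range(1, int(n) + 1):
                sample_to_pop[f"{pop}_{i}"] = pop
        return PopulationMap(sample_to_pop, dict(self.pop_groups))


def inject_sweep(config: SimulationConfig, spec: SweepSpec) -> SimulationConfig:
    """Return a config with one more designated sweep region."""
    import copy
    cfg = copy.deepcopy(config)
    cfg.sweeps = list(cfg.sweeps) + [spec]
    return cfg


def inject_diagnostic_locus(config: SimulationConfig, spec: DiagnosticSpec) -> SimulationConfig:
    """Return a config with one more diagnostic-locus injection."""
    import copy
    cfg = copy.deepcopy(config)
    cfg.diagnostics = list(cfg.diagnostics) + [spec]
    return cfg


@dataclass
class TruthRecord:
    """Ground truth emitted alongside a synthetic cohort."""

    windows: list        # dicts: scaffold, start, end, label, tmrca
    diagnostics: list    # dicts: scaffold, pos, var_class, group
    params: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["windows"], d["diagnostics"], d["params"])

    def window_labels(self) -> dict:
        return {(w["scaffold"], w["start"], w["end"]): w["label"] for w in self.windows}


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _gt_codes_from_mask(mask: int, n_hap: int) -> np.ndarray:
    nbytes = (n_hap + 7) // 8
    bits = np.unpackbits(np.frombuffer(mask.to_bytes(nbytes, "little"), dtype=np.uint8),
                         bitorder="little")[:n_hap]
    return (bits[0::2] + bits[1::2]).astype(np.int8)


def _f32(x: float) -> float:
    # store annotation floats at float32 precision so VCF round-trips exactly
    return float(np.float32(x))


def simulate_cohort(config: SimulationConfig):
    """Simulate the full cohort; returns ``(VariantTable, TruthRecord)``.

    Each ``segment_bp`` window gets an independent genealogy; haplotypes
    are paired into diploids in sample order; genotypes receive the
    configured missingness, synthesized read depths / allele depths, and
    QC annotations drawn from hard-filter-passing ranges (a configurable
    fraction drawn failing instead). Output is deterministic given the
    seed.
    """
    model = config.resolved_model()
    cd = _compiled(model)
    popmap = config.popmap()
    samples = list(popmap.sample_to_pop)
    n_samples = len(samples)
    n_hap = 2 * n_samples

    # leaf h = 2*si + {0,1} belongs to the deme of sample si's population
    deme_names = list(dict.fromkeys(config.pop_deme[p] for p in config.populations))
    deme_idx = {d: cd.pop_names.index(d) for d in deme_names}
    leaf_init = []
    for si, s in enumerate(samples):
        p = deme_idx[config.pop_deme[popmap.sample_to_pop[s]]]
        leaf_init.append((p, 1 << (2 * si)))
        leaf_init.append((p, 1 << (2 * si + 1)))

    master = random.Random(config.seed)
    scaffold_lengths = {f"scaffold_{i + 1}": config.scaffold_length
                        for i in range(config.n_scaffolds)}

    rows, gts, adr, ada, sdp = [], [], [], [], []
    windows_truth = []
    diag_truth = []
    occupied = {}  # scaffold -> set of 1-based positions

    sweeps_by_scaf = {}
    for sp in config.sweeps:
        sweeps_by_scaf.setdefault(sp.scaffold, []).append(sp)
    cd_sweep_cache = {}

    for scaf, length in scaffold_lengths.items():
        occupied[scaf] = set()
        for seg_start in range(0, length - config.segment_bp + 1, config.segment_bp):
            seg_end = seg_start + config.segment_bp
            factor = 1.0
            for sp in sweeps_by_scaf.get(scaf, []):
                if sp.start < seg_end and seg_start < sp.end:
                    factor = max(factor, sp.factor)
            if factor > 1.0:
                if factor not in cd_sweep_cache:
                    present = [d for d in DOMESTIC_DEMES if d in cd.pop_names]
                    cd_sweep_cache[factor] = cd.scaled_sizes(present, factor)
                cd_seg = cd_sweep_cache[factor]
            else:
                cd_seg = cd
            rng = random.Random(master.randrange(2 ** 31))
            branches = []
            tmrca = _run_coalescent(cd_seg, leaf_init, rng, branches=branches)
            gen = Genealogy(branches, [p for p, _ in leaf_init], tmrca)
            muts = drop_mutations(gen, config.theta_site, config.segment_bp, rng)
            windows_truth.append({
                "scaffold": scaf, "start": seg_start, "end": seg_end,
                "label": "sweep" if factor > 1.0 else "neutral",
                "tmrca": tmrca, "factor": factor,
            })
            for pos0, mask in muts:
                pos1 = seg_start + pos0 + 1
                if pos1 in occupied[scaf]:
                    continue
                occupied[scaf].add(pos1)
                codes = _gt_codes_from_mask(mask, n_hap)
                _append_variant(rows, gts, adr, ada, sdp, scaf, pos1, codes,
                                config, rng)

    # diagnostic loci: fixed hom-alt in the target group, hom-ref elsewhere
    group_samples = {g: set(popmap.samples_in_group(g)) for g in popmap.group_labels}
    rng_diag = random.Random(master.randrange(2 ** 31))
    for spec in config.diagnostics:
        targets = group_samples.get(spec.group)
        if not targets:
            raise ValueError(f"diagnostic group {spec.group!r} has no samples")
        classes = spec.var_classes or ["SNP"] * len(spec.positions)
        for pos1, vclass in zip(spec.positions, classes):
            scaf = spec.scaffold
            if scaf not in occupied:
                raise ValueError(f"diagnostic scaffold {scaf!r} not simulated")
            shifted = pos1
            while shifted in occupied[scaf]:
                shifted += 1
            if shifted != pos1:
                logger.info("diagnostic position %s:%d occupied; shifted to %d",
                            scaf, pos1, shifted)
            occupied[scaf].add(shifted)
            codes = np.array([2 if s in targets else 0 for s in samples], dtype=np.int8)
            _append_variant(rows, gts, adr, ada, sdp, scaf, shifted, codes,
                            config, rng_diag, force_class=vclass, no_missing=True)
            diag_truth.append({"scaffold": scaf, "pos": shifted,
                               "var_class": vclass, "group": spec.group})

    sites = pd.DataFrame(rows, columns=list(SITE_COLUMNS)) if rows else pd.DataFrame(
        columns=list(SITE_COLUMNS))
    table = VariantTable(
        samples=samples,
        sites=sites,
        gt=np.vstack(gts).astype(np.int8) if gts else np.zeros((0, n_samples), np.int8),
        ad_ref=np.vstack(adr) if adr else None,
        ad_alt=np.vstack(ada) if ada else None,
        sample_dp=np.vstack(sdp) if sdp else None,
        scaffold_lengths=scaffold_lengths,
    ).sort()
    truth = TruthRecord(
        windows=windows_truth,
        diagnostics=diag_truth,
        params={
            "seed": config.seed, "n_ref": config.n_ref, "mu": config.mu,
            "theta_site": config.theta_site, "segment_bp": config.segment_bp,
            "missingness": config.missingness,
            "populations": dict(config.populations),
            "sweeps": [asdict(s) for s in config.sweeps],
        },
    )
    return table, truth


def _append_variant(rows, gts, adr, ada, sdp, scaf, pos1, codes, config, rng,
                    force_class=None, no_missing=False):
    n_samples = codes.shape[0]
    codes = codes.copy()
    if not no_missing and config.missingness > 0:
        for i in range(n_samples):
            if rng.random() < config.missingness:
                codes[i] = -1

    if force_class is not None:
        vclass = force_class
    else:
        vclass = "INDEL" if rng.random() < config.indel_fraction else "SNP"
    if vclass == "SNP":
        ref = rng.choice(_BASES)
        alt = rng.choice([b for b in _BASES if b != ref])
        ilen = 0
    else:
        ilen = 1
        while rng.random() > config.indel_p1 and ilen < 50:
            ilen += 1
        anchor = rng.choice(_BASES)
        tail = "".join(rng.choice(_BASES) for _ in range(ilen))
        if rng.random() < config.deletion_prob:
            ref, alt, ilen = anchor + tail, anchor, -ilen
        else:
            ref, alt = anchor, anchor + tail

    dp = np.zeros(n_samples, np.int32)
    ref_d = np.zeros(n_samples, np.int32)
    alt_d = np.zeros(n_samples, np.int32)
    for i in range(n_samples):
        c = codes[i]
        if c < 0:
            dp[i] = ref_d[i] = alt_d[i] = -1
            continue
        d = max(1, _poisson(config.mean_depth, rng))
        dp[i] = d
        if c == 0:
            ref_d[i] = d
        elif c == 2:
            alt_d[i] = d
        else:
            a = sum(1 for _ in range(d) if rng.random() < 0.5)
            alt_d[i], ref_d[i] = a, d - a

    fail = rng.random() < config.qc_fail_fraction
    if vclass == "SNP":
        qc = {
            "QUAL": rng.uniform(31.0, 1500.0),
            "QD": rng.uniform(5.5, 35.0),
            "FS": rng.uniform(0.0, 55.0),
            "MQ": rng.uniform(41.0, 60.0),
            "MQRankSum": rng.uniform(-5.0, 5.0),
            "ReadPosRankSum": rng.uniform(-5.0, 5.0),
        }
        failures = {"QUAL": 10.0, "QD": 4.0, "FS": 80.0, "MQ": 30.0,
                    "MQRankSum": -13.0, "ReadPosRankSum": -9.0}
    else:
        qc = {
            "QUAL": rng.uniform(31.0, 1500.0),
            "QD": rng.uniform(5.5, 35.0),
            "FS": rng.uniform(0.0, 180.0),
            "MQ": rng.uniform(41.0, 60.0),
            "MQRankSum": rng.uniform(-5.0, 5.0),
            "ReadPosRankSum": rng.uniform(-15.0, 5.0),
        }
        failures = {"QUAL": 10.0, "QD": 4.0, "FS": 250.0,
                    "ReadPosRankSum": -21.0}
    if fail:
        key = rng.choice(sorted(failures))
        qc[key] = failures[key]

    row = {
        "scaffold": scaf, "pos": int(pos1), "ref": ref, "alt": alt,
        "var_class": vclass, "indel_len": int(ilen),
        "QUAL": _f32(round(qc["QUAL"], 2)),
        "DP": int(dp[dp > 0].sum()) if (dp > 0).any() else 0,
    }
    for f in QC_FIELDS:
        if f == "DP":
            continue
        row[f] = _f32(round(qc[f], 3))
    rows.append(row)
    gts.append(codes)
    adr.append(ref_d)
    ada.append(alt_d)
    sdp.append(dp)


def write_synthetic_genes(scaffold_lengths: dict, path, gene_length: int = 2_000,
                          spacing: int = 3_000) -> int:
    """Write a deterministic synthetic gene track as GFF3 (for annotation tests).

    Genes tile each scaffold with the given length and inter-gene
    spacing. Returns the number of genes written.
    """
    n = 0
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for scaf, length in scaffold_lengths.items():
            fh.write(f"##sequence-region {scaf} 1 {length}\n")
            start = 1
            while start + gene_length - 1 <= length:
                n += 1
                fh.write(f"{scaf}\tanaspop\tgene\t{start}\t{start + gene_length - 1}"
                         f"\t.\t+\t.\tID=gene{n:05d};Name=gene{n:05d}\n")
                start += gene_length + spacing
    return n
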