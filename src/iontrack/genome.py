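"""Coarse voxelized chromatin target and strand-break induction.

The genome is laid out as a randomized walk on a 50 nm lattice confined
to the spherical nucleus: each occupied voxel represents one stackable
chromatin-fiber element holding ``bp_per_voxel`` base pairs (default
5500, the midpoint of 5-6 kbp per element).  Chromosome territories are
connected voxel sets; the genomic coordinate increases monotonically
along each chromosome's walk.  Loop (~100 kbp) and domain (1 Mbp)
boundaries are recorded as genomic bookkeeping.

Break induction rules:

* **Direct** - an energy deposit inside an occupied voxel strikes the
  DNA with probability ``f_dna``; struck deposits are assigned a
  (bp, strand) sugar-phosphate group by projecting the deposit onto the
  local walk direction (sub-voxel bp offset) with a coin-flip strand.
  Energies accumulate per group per exposure; each group then breaks
  with a probability rising linearly from 0 at 5 eV to 1 at 37.5 eV.

* **Indirect** - non-DNA deposits spawn an *OH-radical surrogate* with
  probability ``p_oh``; the radical performs an isotropic random walk
  (fixed step, finite lifetime standing in for scavenging).  On
  entering an occupied voxel it encounters the deoxyribose with
  probability ``p_deoxy``, and 65% of those encounters produce a strand
  break.  A per-voxel cap on radical origins per track stands in for
  radical-radical recombination in dense track cores.

* **Conversion** - each strand break additionally gains an
  opposite-strand partner at the same bp with probability 1%.

Break lists are pandas DataFrames with columns ``chromosome`` (int),
``pos`` (1-based bp, int), ``strand`` (0 = plus, 1 = minus), ``origin``
({direct, indirect, converted}) and ``track_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import NucleusGeometry, RunFrame
from .transport import Deposits

__all__ = [
    "ChromatinModel",
    "DamageParams",
    "build_nucleus_model",
    "dna_mass_per_slab",
    "direct_sb_probability",
    "deposits_to_direct_breaks",
    "indirect_breaks",
    "induce_breaks",
    "convert_sb_to_dsb",
    "empty_breaks",
    "write_breaks",
    "read_breaks",
]

VOXEL_SIZE_UM = 0.05
BREAK_COLUMNS = ["chromosome", "pos", "strand", "origin", "track_id"]

#: Direct strand-break ramp (eV): zero below, certain above.
SB_RAMP_LO_EV = 5.0
SB_RAMP_HI_EV = 37.5

#: Fraction of deoxyribose-radical encounters that yield a strand break.
OH_DEOXYRIBOSE_BREAK_PROB = 0.65

#: SB -> DSB conversion probability (radical transfer surrogate).
SB_TO_DSB_PROB = 0.01

_NEIGHBOR_STEPS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int32,
)


@dataclass
class DamageParams:
    """Tunable surrogate parameters of the damage model.

    Defaults are calibrated once so that a uniform low-LET exposure
    yields roughly 60 direct and 100 indirect strand breaks per Gy per
    Gbp (see docs/methods.md); they are knobs of the surrogate, not
    measured quantities.
    """

    f_dna: float = 0.030          # P(deposit in occupied voxel strikes DNA)
    p_oh: float = 0.25            # P(non-DNA deposit spawns an OH surrogate)
    oh_step_um: float = 0.012     # radical random-walk step length
    oh_max_steps: int = 8         # walk length (scavenging lifetime)
    p_deoxy: float = 0.026        # P(deoxyribose encounter per visited voxel)
    k_max_radicals_per_voxel: int = 12   # density cap per (voxel, track)
    sb_to_dsb: float = SB_TO_DSB_PROB


def empty_breaks() -> pd.DataFrame:
    return pd.DataFrame({
        "chromosome": pd.Series(dtype=np.int64),
        "pos": pd.Series(dtype=np.int64),
        "strand": pd.Series(dtype=np.int8),
        "origin": pd.Series(dtype=object),
        "track_id": pd.Series(dtype=np.int64),
    })


@dataclass
class ChromatinModel:
    """Voxel walk of the genome inside the nucleus.

    ``voxel_ijk`` lists lattice cells in walk order; ``chrom_id`` and
    ``bp_start`` give each voxel's chromosome and its first (1-based)
    bp within that chromosome.  ``grid`` maps lattice cells back to
    walk indices (-1 = unoccupied).
    """

    voxel_size: float
    nucleus_radius: float
    bp_per_voxel: int
    voxel_ijk: np.ndarray          # (N, 3) int32, walk order
    chrom_id: np.ndarray           # (N,) int32
    grid: np.ndarray               # (n, n, n) int32 -> walk index or -1
    chrom_lengths_bp: np.ndarray   # per chromosome
    walk_dir: np.ndarray = field(init=False)   # (N, 3) float unit vectors
    bp_start: np.ndarray = field(init=False)   # (N,) int64
    loop_bp: int = 100_000
    domain_bp: int = 1_000_000

    def __post_init__(self) -> None:
        n = len(self.voxel_ijk)
        # per-chromosome running bp offsets
        bp = np.zeros(n, dtype=np.int64)
        new_chrom = np.empty(n, dtype=bool)
        new_chrom[0] = True
        new_chrom[1:] = self.chrom_id[1:] != self.chrom_id[:-1]
        idx_in_chrom = np.arange(n) - np.maximum.accumulate(
            np.where(new_chrom, np.arange(n), 0))
        bp[:] = idx_in_chrom * self.bp_per_voxel + 1
        self.bp_start = bp
        # local walk direction: towards the next voxel of the same
        # chromosome when lattice-adjacent, else from the previous one
        d = np.zeros((n, 3), dtype=float)
        diff_next = np.zeros((n, 3), dtype=np.int32)
        diff_next[:-1] = self.voxel_ijk[1:] - self.voxel_ijk[:-1]
        same_next = np.zeros(n, dtype=bool)
        same_next[:-1] = self.chrom_id[1:] == self.chrom_id[:-1]
        adj_next = same_next & (np.abs(diff_next).sum(axis=1) == 1)
        d[adj_next] = diff_next[adj_next]
        prev_ok = np.zeros(n, dtype=bool)
        prev_ok[1:] = (~adj_next[1:]) & (self.chrom_id[1:] == self.chrom_id[:-1])
        d[prev_ok] = (self.voxel_ijk[np.where(prev_ok)[0]]
                      - self.voxel_ijk[np.where(prev_ok)[0] - 1])
        norms = np.linalg.norm(d, axis=1)
        fallback = norms == 0
        d[fallback] = [0.0, 0.0, 1.0]
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        self.walk_dir = d

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_ijk)

    @property
    def genome_length(self) -> int:
        """Actual represented genome (bp): voxel count x bp per voxel."""
        return self.n_voxels * self.bp_per_voxel

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_lengths_bp)

    def voxel_centers(self) -> np.ndarray:
        """Voxel centre coordinates (um) in the model frame."""
        n = self.grid.shape[0]
        return (self.voxel_ijk + 0.5) * self.voxel_size - n * self.voxel_size / 2.0

    def locate(self, points_um: np.ndarray) -> np.ndarray:
        """Walk indices of the voxels containing points (-1 if empty/out)."""
        n = self.grid.shape[0]
        ijk = np.floor(points_um / self.voxel_size + n / 2.0).astype(np.int64)
        ok = np.all((ijk >= 0) & (ijk < n), axis=1)
        out = np.full(len(points_um), -1, dtype=np.int64)
        sel = ijk[ok]
        out[ok] = self.grid[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out

    def domain_boundaries(self, chrom: int) -> np.ndarray:
        """Genomic positions of 1-Mbp chromatin-domain boundaries."""
        L = int(self.chrom_lengths_bp[chrom])
        return np.arange(self.domain_bp, L, self.domain_bp, dtype=np.int64)

    def loop_boundaries(self, chrom: int) -> np.ndarray:
        """Genomic positions of ~100-kbp fiber-loop boundaries."""
        L = int(self.chrom_lengths_bp[chrom])
        return np.arange(self.loop_bp, L, self.loop_bp, dtype=np.int64)


def _grow_walk_py(grid, n, counts, order, chrom_of, seed):  # pragma: no cover
    """Pure-python reference of the numba walk kernel (kept for clarity
    and as a fallback when numba is unavailable)."""
    np.random.seed(seed)
    w = 0
    for c in range(len(counts)):
        while True:
            i, j, k = (np.random.randint(0, n) for _ in range(3))
            if grid[i, j, k] == -1:
                break
        cur = (i, j, k)
        grid[cur] = w
        order[w] = cur
        chrom_of[w] = c
        w += 1
        chrom_start = w - 1
        resume = w - 1
        for _ in range(int(counts[c]) - 1):
            nxt = _free_neighbor(grid, n, cur)
            if nxt is None:
                nxt = None
                for back in range(resume, chrom_start - 1, -1):
                    nxt = _free_neighbor(grid, n, tuple(order[back]))
                    if nxt is not None:
                        resume = back
                        break
                if nxt is None:
                    # territory fully enclosed: start a fresh component
                    tries = 0
                    while nxt is None and tries < 1_000_000:
                        i, j, k = (np.random.randint(0, n) for _ in range(3))
                        if grid[i, j, k] == -1:
                            nxt = (i, j, k)
                        tries += 1
                    if nxt is None:
                        return False
            cur = nxt
            grid[cur] = w
            order[w] = cur
            chrom_of[w] = c
            w += 1
            resume = w - 1
    return True


def _free_neighbor(grid, n, cur):  # pragma: no cover
    cands = []
    for dx, dy, dz in _NEIGHBOR_STEPS:
        x, y, z = cur[0] + dx, cur[1] + dy, cur[2] + dz
        if 0 <= x < n and 0 <= y < n and 0 <= z < n and grid[x, y, z] == -1:
            cands.append((x, y, z))
    if not cands:
        return None
    return cands[np.random.randint(0, len(cands))]


try:
    from numba import njit

    @njit(cache=False)
    def _grow_walk(grid, n, counts, order, chrom_of, seed):
        np.random.seed(seed)
        w = 0
        fx = np.empty(6, dtype=np.int64)
        fy = np.empty(6, dtype=np.int64)
        fz = np.empty(6, dtype=np.int64)
        dxs = np.array([1, -1, 0, 0, 0, 0], dtype=np.int64)
        dys = np.array([0, 0, 1, -1, 0, 0], dtype=np.int64)
        dzs = np.array([0, 0, 0, 0, 1, -1], dtype=np.int64)
        for c in range(len(counts)):
            while True:
                i = np.random.randint(0, n)
                j = np.random.randint(0, n)
                k = np.random.randint(0, n)
                if grid[i, j, k] == -1:
                    break
            cx, cy, cz = i, j, k
            grid[cx, cy, cz] = w
            order[w, 0], order[w, 1], order[w, 2] = cx, cy, cz
            chrom_of[w] = c
            w += 1
            chrom_start = w - 1
            resume = w - 1
            for _ in range(counts[c] - 1):
                nf = 0
                for t in range(6):
                    x = cx + dxs[t]
                    y = cy + dys[t]
                    z = cz + dzs[t]
                    if (0 <= x < n and 0 <= y < n and 0 <= z < n
                            and grid[x, y, z] == -1):
                        fx[nf], fy[nf], fz[nf] = x, y, z
                        nf += 1
                if nf == 0:
                    found = False
                    for back in range(resume, chrom_start - 1, -1):
                        bx = order[back, 0]
                        by = order[back, 1]
                        bz = order[back, 2]
                        for t in range(6):
                            x = bx + dxs[t]
                            y = by + dys[t]
                            z = bz + dzs[t]
                            if (0 <= x < n and 0 <= y < n and 0 <= z < n
                                    and grid[x, y, z] == -1):
                                fx[nf], fy[nf], fz[nf] = x, y, z
                                nf += 1
                        if nf > 0:
                            resume = back
                            found = True
                            break
                    if not found:
                        # fully enclosed territory: new component at a
                        # random free cell (rare at default occupancy)
                        tries = 0
                        while nf == 0 and tries < 1_000_000:
                            x = np.random.randint(0, n)
                            y = np.random.randint(0, n)
                            z = np.random.randint(0, n)
                            if grid[x, y, z] == -1:
                                fx[0], fy[0], fz[0] = x, y, z
                                nf = 1
                            tries += 1
                        if nf == 0:
                            return False
                pick = np.random.randint(0, nf)
                cx, cy, cz = fx[pick], fy[pick], fz[pick]
                grid[cx, cy, cz] = w
                order[w, 0], order[w, 1], order[w, 2] = cx, cy, cz
                chrom_of[w] = c
                w += 1
                resume = w - 1
        return True
except ImportError:  # pragma: no cover
    _grow_walk = _grow_walk_py


def _chromosome_voxel_counts(n_voxels: int, bp_per_voxel: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Split the genome into chromosomes of ~50-245 Mbp (scaled down for
    small test genomes), totalling exactly ``n_voxels`` voxels."""
    genome_bp = n_voxels * bp_per_voxel
    n_chrom = int(np.clip(round(genome_bp / 139e6), 1, 46))
    w = rng.uniform(50.0, 245.0, n_chrom)
    counts = np.maximum(1, np.round(w / w.sum() * n_voxels).astype(int))
    # fix rounding drift
    while counts.sum() != n_voxels:
        i = int(rng.integers(n_chrom))
        if counts.sum() > n_voxels and counts[i] > 1:
            counts[i] -= 1
        elif counts.sum() < n_voxels:
            counts[i] += 1
    return counts


def build_nucleus_model(
    geometry: NucleusGeometry,
    genome_length: float = 6.4e9,
    seed: int = 0,
    bp_per_voxel: int = 5500,
) -> ChromatinModel:
    """Grow the chromatin walk inside the spherical nucleus.

    Each chromosome is grown as a self-avoiding-ish lattice walk: steps
    go to uniformly chosen free 6-neighbours; when walled in, the walk
    resumes from the most recent voxel of the same chromosome that
    still has a free neighbour (keeping the territory connected).  In
    the rare event that an entire territory is enclosed, a fresh
    component is started at a random free cell, so a chromosome
    occasionally splits into a handful of connected components.

    Raises ``ValueError`` when the genome does not fit (occupied
    fraction of the sphere's lattice cells above ~0.85, where walk
    growth becomes infeasible).
    """
    rng = np.random.default_rng(seed)
    r_um = geometry.nucleus_radius
    n = int(np.ceil(2 * r_um / VOXEL_SIZE_UM))
    centers_1d = (np.arange(n) + 0.5) * VOXEL_SIZE_UM - n * VOXEL_SIZE_UM / 2
    ii, jj, kk = np.meshgrid(centers_1d, centers_1d, centers_1d,
                             indexing="ij")
    inside = (ii**2 + jj**2 + kk**2) <= r_um**2
    n_cells = int(inside.sum())
    n_voxels = int(round(genome_length / bp_per_voxel))
    if n_voxels < 1:
        raise ValueError("genome shorter than one voxel")
    if n_voxels > 0.85 * n_cells:
        raise ValueError(
            f"genome needs {n_voxels} voxels but only {n_cells} lattice "
            "cells fit in the nucleus (occupancy cap 0.85)"
        )

    grid = np.where(inside, -1, -2).astype(np.int32)  # -2 = outside sphere
    counts = _chromosome_voxel_counts(n_voxels, bp_per_voxel, rng)
    order = np.empty((n_voxels, 3), dtype=np.int32)
    chrom_of = np.empty(n_voxels, dtype=np.int32)
    ok = _grow_walk(grid, np.int64(n), counts.astype(np.int64), order,
                    chrom_of, np.int64(rng.integers(2**31)))
    if not ok:
        raise ValueError(
            "chromatin walk walled in; genome too dense for the nucleus "
            "volume"
        )
    grid[grid == -2] = -1
    return ChromatinModel(
        voxel_size=VOXEL_SIZE_UM,
        nucleus_radius=r_um,
        bp_per_voxel=bp_per_voxel,
        voxel_ijk=order,
        chrom_id=chrom_of,
        grid=grid,
        chrom_lengths_bp=counts.astype(np.int64) * bp_per_voxel,
    )


def dna_mass_per_slab(
    model: ChromatinModel,
    geometry: NucleusGeometry,
    n_rotations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean bp content of each beam-depth slab over random nucleus rotations."""
    if n_rotations < 1:
        raise ValueError("need at least one rotation")
    from .geometry import random_rotation

    centers = model.voxel_centers()
    r = geometry.nucleus_radius
    n_slabs = geometry.n_slabs
    dz = geometry.slab_thickness
    acc = np.zeros(n_slabs)
    for _ in range(n_rotations):
        rot = random_rotation(rng)
        z = centers @ rot[2]  # z-component after rotation
        idx = np.clip(((z + r) / dz).astype(int), 0, n_slabs - 1)
        acc += np.bincount(idx, minlength=n_slabs)
    return acc / n_rotations * model.bp_per_voxel


def direct_sb_probability(energy_ev):
    """Break probability of a sugar-phosphate group vs accumulated energy.

    Linear ramp: 0 at <= 5 eV, 1 at >= 37.5 eV.
    """
    e = np.asarray(energy_ev, dtype=float)
    p = np.clip((e - SB_RAMP_LO_EV) / (SB_RAMP_HI_EV - SB_RAMP_LO_EV),
                0.0, 1.0)
    return p if p.ndim else float(p)


def _assign_groups(model: ChromatinModel, points: np.ndarray,
                   voxel_idx: np.ndarray,
                   rng: np.random.Generator):
    """Map hit points to (chromosome, bp, strand) sugar-phosphate groups.

    The bp offset inside the voxel is the longitudinal fraction of the
    point along the voxel's local walk direction; the strand is an even
    coin flip.
    """
    vi = voxel_idx
    centers = (model.voxel_ijk[vi] + 0.5) * model.voxel_size \
        - model.grid.shape[0] * model.voxel_size / 2.0
    t = np.einsum("ij,ij->i", points - centers, model.walk_dir[vi])
    frac = np.clip(t / model.voxel_size + 0.5, 0.0, 1.0 - 1e-12)
    bp = model.bp_start[vi] + (frac * model.bp_per_voxel).astype(np.int64)
    chrom = model.chrom_id[vi]
    strand = rng.integers(0, 2, len(vi)).astype(np.int8)
    return chrom, bp, strand


def deposits_to_direct_breaks(
    deposits: Deposits,
    model: ChromatinModel,
    params: DamageParams,
    rng: np.random.Generator,
    frame: RunFrame | None = None,
    dna_hit_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Direct strand breaks from energy deposits striking the DNA.

    Deposit positions are mapped into the model frame (via ``frame``),
    located on the chromatin lattice, thinned by ``f_dna``, assigned to
    sugar-phosphate groups, and accumulated per group; each group then
    breaks with :func:`direct_sb_probability` of its total energy.
    ``dna_hit_mask`` (as produced by :func:`induce_breaks`) can supply
    the DNA-hit thinning externally so the indirect route sees a
    consistent complement.
    """
    if len(deposits) == 0:
        return empty_breaks()
    pts = deposits.position if frame is None else frame.to_model_frame(
        deposits.position)
    vi = model.locate(pts)
    if dna_hit_mask is None:
        dna_hit_mask = (vi >= 0) & (rng.random(len(deposits)) < params.f_dna)
    hits = np.where(dna_hit_mask)[0]
    if hits.size == 0:
        return empty_breaks()
    chrom, bp, strand = _assign_groups(model, pts[hits], vi[hits], rng)
    df = pd.DataFrame({
        "chromosome": chrom.astype(np.int64),
        "pos": bp,
        "strand": strand,
        "energy": deposits.energy[hits],
        "track_id": deposits.track_id[hits],
    })
    grouped = df.groupby(["chromosome", "pos", "strand"], sort=False).agg(
        energy=("energy", "sum"),
        track_id=("track_id", lambda s: s.iloc[int(np.argmax(
            df.loc[s.index, "energy"].to_numpy()))]),
    ).reset_index()
    p = direct_sb_probability(grouped["energy"].to_numpy())
    broke = rng.random(len(grouped)) < p
    out = grouped.loc[broke, ["chromosome", "pos", "strand", "track_id"]]
    out = out.assign(origin="direct")[BREAK_COLUMNS]
    return out.astype({"chromosome": np.int64, "pos": np.int64,
                       "strand": np.int8, "track_id": np.int64})


def indirect_breaks(
    deposits: Deposits,
    model: ChromatinModel,
    params: DamageParams,
    rng: np.random.Generator,
    frame: RunFrame | None = None,
    dna_hit_mask: np.ndarray | None = None,
    stats: dict | None = None,
) -> pd.DataFrame:
    """Indirect strand breaks via the hydroxyl-radical surrogate.

    When a ``stats`` dict is supplied it receives the counters
    ``radicals``, ``deoxyribose_encounters`` and ``breaks`` (the break
    fraction of encounters converges to 0.65).

    Every deposit that did not strike DNA spawns a radical with
    probability ``p_oh`` (capped per voxel and track to emulate
    radical-radical recombination in dense cores); radicals random-walk
    and, upon visiting occupied voxels, encounter deoxyribose with
    probability ``p_deoxy``; 65% of encounters break the strand.
    """
    if len(deposits) == 0 or params.p_oh <= 0:
        return empty_breaks()
    pts = deposits.position if frame is None else frame.to_model_frame(
        deposits.position)
    if dna_hit_mask is None:
        vi0 = model.locate(pts)
        dna_hit_mask = (vi0 >= 0) & (rng.random(len(deposits)) < params.f_dna)
    cand = np.where(~dna_hit_mask)[0]
    cand = cand[rng.random(cand.size) < params.p_oh]
    if cand.size == 0:
        return empty_breaks()

    # per-(voxel, track) density cap on radical origins
    n = model.grid.shape[0]
    ijk = np.floor(pts[cand] / model.voxel_size + n / 2.0).astype(np.int64)
    ijk = np.clip(ijk, 0, n - 1)
    key = ((ijk[:, 0] * n + ijk[:, 1]) * n + ijk[:, 2]) * (
        deposits.track_id.max() + 1) + deposits.track_id[cand]
    order = np.argsort(key, kind="stable")
    sorted_key = key[order]
    new_grp = np.empty(cand.size, dtype=bool)
    new_grp[0] = True
    new_grp[1:] = sorted_key[1:] != sorted_key[:-1]
    grp_id = np.cumsum(new_grp) - 1
    rank = np.arange(cand.size) - np.maximum.accumulate(
        np.where(new_grp, np.arange(cand.size), 0))
    keep = np.empty(cand.size, dtype=bool)
    keep[order] = rank < params.k_max_radicals_per_voxel
    cand = cand[keep]

    pos = pts[cand].copy()
    track = deposits.track_id[cand].copy()
    rows = []
    n_enc = 0
    n_brk = 0
    alive = np.ones(cand.size, dtype=bool)
    for _ in range(params.oh_max_steps):
        if not alive.any():
            break
        idx = np.where(alive)[0]
        step = rng.standard_normal((idx.size, 3))
        step /= np.linalg.norm(step, axis=1, keepdims=True)
        pos[idx] += step * params.oh_step_um
        vi = model.locate(pos[idx])
        occ = vi >= 0
        enc = occ & (rng.random(idx.size) < params.p_deoxy)
        if enc.any():
            sel = idx[enc]
            broke = rng.random(sel.size) < OH_DEOXYRIBOSE_BREAK_PROB
            n_enc += int(sel.size)
            n_brk += int(broke.sum())
            if broke.any():
                bsel = sel[broke]
                chrom, bp, strand = _assign_groups(
                    model, pos[bsel], vi[enc][broke], rng)
                rows.append(pd.DataFrame({
                    "chromosome": chrom.astype(np.int64),
                    "pos": bp,
                    "strand": strand,
                    "origin": "indirect",
                    "track_id": track[bsel],
                }))
            alive[sel] = False  # consumed by the deoxyribose reaction
    if stats is not None:
        stats.update(radicals=int(cand.size),
                     deoxyribose_encounters=n_enc, breaks=n_brk)
    if not rows:
        return empty_breaks()
    return pd.concat(rows, ignore_index=True)[BREAK_COLUMNS]


def convert_sb_to_dsb(breaks: pd.DataFrame, rng: np.random.Generator,
                      prob: float = SB_TO_DSB_PROB) -> pd.DataFrame:
    """Give each break, with the stated probability, an opposite-strand
    partner at the same position (origin ``converted``); input rows are
    preserved."""
    if len(breaks) == 0 or prob <= 0:
        return breaks
    pick = rng.random(len(breaks)) < prob
    partners = breaks.loc[pick].copy()
    partners["strand"] = (1 - partners["strand"]).astype(np.int8)
    partners["origin"] = "converted"
    return pd.concat([breaks, partners], ignore_index=True)


def induce_breaks(
    deposits: Deposits,
    model: ChromatinModel,
    params: DamageParams,
    rng: np.random.Generator,
    frame: RunFrame | None = None,
) -> pd.DataFrame:
    """Full induction chain: direct + indirect breaks, then 1% SB->DSB
    conversion, with a consistent DNA-hit split between the routes."""
    if len(deposits) == 0:
        return empty_breaks()
    pts = deposits.position if frame is None else frame.to_model_frame(
        deposits.position)
    vi = model.locate(pts)
    mask = (vi >= 0) & (rng.random(len(deposits)) < params.f_dna)
    direct = deposits_to_direct_breaks(deposits, model, params, rng,
                                       frame=frame, dna_hit_mask=mask)
    indirect = indirect_breaks(deposits, model, params, rng,
                               frame=frame, dna_hit_mask=mask)
    breaks = pd.concat([direct, indirect], ignore_index=True)
    return convert_sb_to_dsb(breaks, rng, params.sb_to_dsb)


def write_breaks(breaks: pd.DataFrame, path) -> None:
    """Write a break list as TSV (strand as plus/minus)."""
    out = breaks.copy()
    out["strand"] = np.where(out["strand"].to_numpy() == 0, "plus", "minus")
    out.to_csv(path, sep="\t", index=False)


def read_breaks(path) -> pd.DataFrame:
    """Read a break-list TSV (chromosome, pos, strand, origin, track_id)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(BREAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"break list missing columns: {sorted(missing)}")
    strand = df["strand"]
    if strand.dtype == object:
        df["strand"] = np.where(strand.str.lower().isin(["plus", "+", "0"]),
                                0, 1).astype(np.int8)
    return df[BREAK_COLUMNS].astype({"chromosome": np.int64, "pos": np.int64,
                                     "strand": np.int8, "track_id": np.int64})
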