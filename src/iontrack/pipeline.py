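"""Experiment orchestration: multi-run simulation loop, statistics, outputs.

A *run* is one irradiation of the nucleus: a freshly rotated source,
``primaries_per_run`` parallel ions (fluence 0.0625 um^-2 by default),
full slowing-down transport, dose/LET scoring, break induction on the
chromatin model and damage classification.  An *experiment* repeats
runs with independent substreams of one seeded generator and reports
means with uncertainties of twice the standard error of the mean.

Also home of the fixture generator used by the test-suite and the CLI:
deterministic break patterns (including the three canonical 7-DSB
scenarios) and synthetic energy-deposit sets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .barkas import SUPPORTED_IONS, get_ion
from .baseline import BaselineTable, build_default_baseline
from .classify import DEFAULT_FRAGMENT_BINS, classify_breaks
from .genome import (
    ChromatinModel,
    DamageParams,
    build_nucleus_model,
    induce_breaks,
    write_breaks,
)
from .geometry import (
    NucleusGeometry,
    dose_in_nucleus,
    let_from_dose_fluence,
    make_run,
    slab_profile,
)
from .transport import (
    Deposits,
    KernelParams,
    compute_range,
    csda_range,
    simulate_track,
)

__all__ = [
    "RunConfig",
    "ExperimentResult",
    "run_experiment",
    "generate_fixture",
    "FIXTURE_KINDS",
]


@dataclass
class RunConfig:
    """Configuration of a simulation experiment."""

    ion: str = "H"
    energy_mev_u: float = 1.0
    n_runs: int = 16
    seed: int = 0
    geometry: NucleusGeometry = field(default_factory=NucleusGeometry)
    damage: DamageParams = field(default_factory=DamageParams)
    kernel: KernelParams = field(default_factory=KernelParams)
    genome_length: float = 6.4e9
    bp_per_voxel: int = 5500
    slab_profiles: bool = False
    fragment_bins: tuple = DEFAULT_FRAGMENT_BINS
    output_dir: str | None = None

    def validate(self, baseline: BaselineTable) -> None:
        if self.ion not in SUPPORTED_IONS:
            raise ValueError(
                f"unsupported ion {self.ion!r}; choose from "
                f"{sorted(SUPPORTED_IONS)}")
        lo, hi = baseline.span
        if not (max(lo, 0.01) <= self.energy_mev_u <= hi):
            raise ValueError(
                f"energy {self.energy_mev_u} MeV/u outside the supported "
                f"span [{max(lo, 0.01):g}, {hi:g}]")
        if self.n_runs < 1:
            raise ValueError("need at least one run")

    def to_metadata(self) -> dict:
        meta = dataclasses.asdict(self)
        meta["package_version"] = __version__
        return meta


@dataclass
class ExperimentResult:
    """Aggregated output of :func:`run_experiment`."""

    per_run: pd.DataFrame
    summary: pd.DataFrame           # columns: mean, err2sem (2 x SEM)
    slab_mean: pd.DataFrame | None
    dna_per_slab_bp: np.ndarray | None
    metadata: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_run.to_csv(out / "per_run.tsv", sep="\t", index=False)
        self.summary.to_csv(out / "summary.tsv", sep="\t")
        if self.slab_mean is not None:
            self.slab_mean.to_csv(out / "slab_profile.tsv", sep="\t",
                                  index=False)
        with open(out / "metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)


def run_experiment(config: RunConfig,
                   baseline: BaselineTable | None = None,
                   model: ChromatinModel | None = None) -> ExperimentResult:
    """Execute the configured runs and aggregate damage statistics.

    The chromatin model is built once per experiment seed (it can also
    be passed in to share across experiments).  Each run draws from an
    independent child of the experiment seed, so results are exactly
    reproducible for a given configuration.
    """
    baseline = baseline or build_default_baseline()
    config.validate(baseline)
    ion = get_ion(config.ion)
    geo = config.geometry
    if model is None:
        model = build_nucleus_model(geo, config.genome_length,
                                    seed=config.seed,
                                    bp_per_voxel=config.bp_per_voxel)

    # stoppers: dose volume reduced to the spherical cap of the range.
    # The cap height uses the full slowing-down path length so that the
    # Bragg-peak deposits at the very end of the track stay inside the
    # averaging volume; the 10%-extrapolation range is the reported
    # range observable.
    range_um = compute_range(ion, config.energy_mev_u, baseline)
    cap_range = csda_range(ion, config.energy_mev_u, baseline)
    cap = cap_range if cap_range < geo.nucleus_diameter else None

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_runs)
    rows = []
    slab_acc = None
    for i_run, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        frame, states = make_run(geo, ion, config.energy_mev_u, rng,
                                 seed=config.seed)
        tracks = [
            simulate_track(st, baseline, rng,
                           scoring_radius=geo.scoring_radius,
                           kernel=config.kernel, track_id=t)
            for t, st in enumerate(states)
        ]
        deposits = Deposits.concat([t.deposits for t in tracks])
        d_gy = dose_in_nucleus(deposits, geo, cap_height_um=cap)
        let = let_from_dose_fluence(d_gy, geo.fluence)
        breaks = induce_breaks(deposits, model, config.damage, rng,
                               frame=frame)
        summary, sites, dsb, ssb = classify_breaks(
            breaks, dose_gy=d_gy, genome_length_bp=model.genome_length,
            fragment_bins=config.fragment_bins)
        row = {
            "run": i_run,
            "dose_Gy": d_gy,
            "let_keV_um": let,
            "n_stopped": sum(t.stopped_inside for t in tracks),
            "sb": summary.sb,
            "ssb": summary.ssb,
            "dsb": summary.dsb,
            "isolated_dsb": summary.isolated_dsb,
            "dsb_clusters": summary.dsb_clusters,
            "dsb_sites": summary.dsb_sites,
            "multiplicity": summary.multiplicity,
            "micro_fragments": summary.micro_fragments,
        }
        for label, count in summary.fragment_counts.items():
            row[f"frag {label}"] = count
        rows.append(row)
        if config.slab_profiles:
            prof = slab_profile(deposits, geo, geo.fluence)
            slab_acc = prof if slab_acc is None else slab_acc.add(
                prof, fill_value=0.0)

    per_run = pd.DataFrame(rows)
    n = len(per_run)
    numeric = per_run.drop(columns=["run"])
    mean = numeric.mean()
    if n > 1:
        err = 2.0 * numeric.std(ddof=1) / np.sqrt(n)
    else:
        err = pd.Series(np.nan, index=numeric.columns)  # SEM undefined
    summary_df = pd.DataFrame({"mean": mean, "err2sem": err})
    summary_df.index.name = "quantity"

    slab_mean = None
    dna_slab = None
    if config.slab_profiles and slab_acc is not None:
        slab_mean = slab_acc / n
        dna_slab = model.dna_per_slab if hasattr(model, "dna_per_slab") else None

    meta = config.to_metadata()
    meta["n_runs_executed"] = n
    meta["range_um"] = range_um
    meta["genome_length_actual_bp"] = int(model.genome_length)
    result = ExperimentResult(per_run, summary_df, slab_mean, dna_slab, meta)
    if config.output_dir:
        result.write(config.output_dir)
    return result


# --- fixture generator -----------------------------------------------------

FIXTURE_KINDS = (
    "worked_example_isolated7",
    "worked_example_2clusters",
    "worked_example_chain7",
    "random_breaks",
    "uniform_deposits",
    "bragg_deposits",
)


def _dsb_pair(chrom, pos, track=0):
    """A clean DSB: plus-strand break at pos, minus-strand 2 bp away."""
    return [(chrom, pos, 0, "direct", track),
            (chrom, pos + 2, 1, "direct", track)]


def worked_example_breaks(kind: str) -> pd.DataFrame:
    """The three canonical 7-DSB patterns as break lists.

    * ``isolated7`` - 7 mutually distant DSB: 7 sites, 0 clusters.
    * ``2clusters`` - two pairs of DSB 20 bp apart (pairs far apart)
      plus 3 distant DSB: 5 sites, 2 clusters of multiplicity 2.
    * ``chain7`` - 7 DSB chained 20 bp apart: 1 site, 1 cluster of
      multiplicity 7.
    """
    rows = []
    if kind == "worked_example_isolated7":
        for i in range(7):
            rows += _dsb_pair(0, 1_000_000 * (i + 1), track=0)
    elif kind == "worked_example_2clusters":
        rows += _dsb_pair(0, 1_000, track=0)
        rows += _dsb_pair(0, 1_020, track=0)
        rows += _dsb_pair(0, 11_000, track=0)
        rows += _dsb_pair(0, 11_020, track=0)
        for i in range(3):
            rows += _dsb_pair(0, 30_000 + 10_000 * i, track=0)
    elif kind == "worked_example_chain7":
        for i in range(7):
            rows += _dsb_pair(0, 1_000 + 20 * i, track=0)
    else:
        raise ValueError(f"not a worked example: {kind!r}")
    return pd.DataFrame(
        rows, columns=["chromosome", "pos", "strand", "origin", "track_id"])


def random_breaks(n: int, genome_length: int, seed: int,
                  n_chromosomes: int = 1) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "chromosome": rng.integers(0, n_chromosomes, n),
        "pos": rng.integers(1, genome_length + 1, n),
        "strand": rng.integers(0, 2, n).astype(np.int8),
        "origin": "direct",
        "track_id": rng.integers(0, 5, n),
    }).sort_values(["chromosome", "pos"], kind="stable").reset_index(drop=True)


def uniform_deposit_set(total_ev: float, radius_um: float, seed: int,
                        mean_ev: float = 50.0) -> Deposits:
    """Uniform synthetic deposits in a sphere (low-LET-like exposure)."""
    rng = np.random.default_rng(seed)
    n = max(1, int(total_ev / mean_ev))
    e = rng.exponential(mean_ev, n)
    e *= total_ev / e.sum()
    p = rng.standard_normal((n, 3))
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    p *= radius_um * (rng.random(n) ** (1.0 / 3.0))[:, None]
    return Deposits(p, e, np.zeros(n, dtype=np.int8),
                    np.zeros(n, dtype=np.int64))


def bragg_deposit_set(ion_name: str, energy_mev_u: float, seed: int,
                      baseline: BaselineTable | None = None,
                      n_rays: int = 600, dz_um: float = 0.02,
                      source_radius_um: float | None = None
                      ) -> tuple[Deposits, float]:
    """Deterministic Bragg-shaped deposit set plus its planar fluence.

    Superposes `n_rays` parallel rays in a low-discrepancy sunflower
    layout on the source disc (seed only rotates the pattern), each
    depositing the deterministic energy-loss profile (scaled stopping x
    step) along the beam depth starting at the source plane z = -5 um.
    Under the dose/fluence LET definition the slab LET of this pattern
    reproduces the depth-dependent stopping power, so it is a clean
    test pattern for slab scoring even in the small polar slabs.
    """
    from .transport import slowing_down_curve

    baseline = baseline or build_default_baseline()
    ion = get_ion(ion_name)
    if source_radius_um is None:
        source_radius_um = float(np.sqrt(80.0 / np.pi))
    rng = np.random.default_rng(seed)
    depth, e = slowing_down_curve(ion, energy_mev_u, baseline)
    grid = np.arange(0.0, min(float(depth[-1]), 10.0), dz_um) + dz_um / 2.0
    e_g = np.interp(grid, depth, e)
    from .barkas import beta_from_energy, scaling_factor
    s = np.asarray(baseline.stopping_at(e_g))
    if ion.Z != 1:
        s = s * scaling_factor(ion.Z, beta_from_energy(e_g))
    seg_ev = s * 1000.0 * dz_um  # eV deposited per ray per depth step
    i = np.arange(n_rays)
    r = source_radius_um * np.sqrt((i + 0.5) / n_rays)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = i * golden + rng.uniform(0.0, 2.0 * np.pi)
    x = np.repeat(r * np.cos(phi), len(grid))
    y = np.repeat(r * np.sin(phi), len(grid))
    z = np.tile(grid - 5.0, n_rays)
    en = np.tile(seg_ev, n_rays)
    track = np.repeat(np.arange(n_rays, dtype=np.int64), len(grid))
    dep = Deposits(np.column_stack([x, y, z]), en,
                   np.zeros(en.size, dtype=np.int8), track)
    fluence = n_rays / (np.pi * source_radius_um**2)
    return dep, fluence


def generate_fixture(kind: str, out_dir, seed: int = 0,
                     **params) -> Path:
    """Write a deterministic fixture file; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if kind.startswith("worked_example"):
        df = worked_example_breaks(kind)
        path = out / f"{kind}.tsv"
        write_breaks(df, path)
    elif kind == "random_breaks":
        df = random_breaks(params.get("n", 200),
                           int(params.get("genome_length", 1_000_000)),
                           seed, params.get("n_chromosomes", 1))
        path = out / "random_breaks.tsv"
        write_breaks(df, path)
    elif kind == "uniform_deposits":
        dep = uniform_deposit_set(params.get("total_ev", 1.0e6),
                                  params.get("radius_um", 5.0), seed)
        path = out / "uniform_deposits.tsv"
        _write_deposits(dep, path)
    elif kind == "bragg_deposits":
        dep, _ = bragg_deposit_set(params.get("ion", "C"),
                                   params.get("energy_mev_u", 0.25), seed)
        path = out / "bragg_deposits.tsv"
        _write_deposits(dep, path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"choose from {FIXTURE_KINDS}")
    return path


def _write_deposits(dep: Deposits, path) -> None:
    pd.DataFrame({
        "x_um": dep.position[:, 0],
        "y_um": dep.position[:, 1],
        "z_um": dep.position[:, 2],
        "energy_eV": dep.energy,
        "kind": dep.kind,
        "track_id": dep.track_id,
    }).to_csv(path, sep="\t", index=False, float_format="%.6g")
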