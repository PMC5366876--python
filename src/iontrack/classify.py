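"""Classification of strand-break patterns into SSB, DSB, clusters, sites
and fragment-size spectra.

Rules, applied in order:

1. **Adjacent-break merging** - same-strand breaks on directly adjacent
   (or identical) nucleotide positions collapse into one break at the
   run's lowest position: multiple breaks are scored individually only
   when at least one unbroken sugar-phosphate group separates them.
2. **DSB calling** - pairs of breaks on opposite strands within 10 bp
   form a double-strand break.  The pairing is greedy and
   deterministic: breaks are scanned by ascending position (plus strand
   first on ties); each unpaired break pairs with the nearest unpaired
   opposite-strand break within 10 bp (ties: lower position, then plus
   strand).  Unpaired breaks are single-strand breaks, including breaks
   in the vicinity of a DSB.
3. **Cluster merging** - DSB whose representative positions chain with
   consecutive separations of at most 25 bp merge into DSB clusters
   (single linkage; clusters may hold more than two DSB).
4. **Sites** - an isolated DSB or one whole cluster is one DSB site: a
   non-local (>10 nm) measure of chromatin breakage.
5. **Fragments** - gaps between consecutive DSB sites of the same track
   on the same chromosome, binned into size intervals that match the
   chromatin hierarchy (nucleosome 60-100 bp, fiber 0.3-3 kbp, loop
   10-100 kbp, domain 0.3-3 Mbp) plus a PFGE-detectable window
   (5 kbp - 6 Mbp).  Sub-25-bp intra-cluster micro-fragments are
   counted separately and never enter the binned spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DSB_MAX_BP",
    "CLUSTER_MAX_BP",
    "DEFAULT_FRAGMENT_BINS",
    "PFGE_BIN",
    "DamageSummary",
    "merge_adjacent",
    "call_dsb",
    "cluster_dsb",
    "summarize",
    "fragment_spectrum",
    "classify_breaks",
]

#: Maximum strand separation (bp) of the two breaks of a DSB.
DSB_MAX_BP = 10
#: Maximum separation (bp) chaining DSB into a cluster.
CLUSTER_MAX_BP = 25

#: (label, lo_bp, hi_bp) closed intervals of the fragment spectrum.
DEFAULT_FRAGMENT_BINS = (
    ("60-100 bp", 60, 100),
    ("0.3-3 kbp", 300, 3_000),
    ("10-100 kbp", 10_000, 100_000),
    ("0.3-3 Mbp", 300_000, 3_000_000),
)
PFGE_BIN = ("5 kbp-6 Mbp", 5_000, 6_000_000)


def merge_adjacent(breaks: pd.DataFrame) -> pd.DataFrame:
    """Collapse same-strand runs at consecutive (or equal) bp positions.

    Keeps the lowest position of each run; idempotent.
    """
    if len(breaks) == 0:
        return breaks.copy()
    df = breaks.sort_values(
        ["chromosome", "strand", "pos"], kind="stable").reset_index(drop=True)
    chrom = df["chromosome"].to_numpy()
    strand = df["strand"].to_numpy()
    pos = df["pos"].to_numpy()
    new_run = np.empty(len(df), dtype=bool)
    new_run[0] = True
    new_run[1:] = ((chrom[1:] != chrom[:-1])
                   | (strand[1:] != strand[:-1])
                   | (pos[1:] - pos[:-1] > 1))
    return df.loc[new_run].reset_index(drop=True)


def call_dsb(breaks: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Greedy DSB pairing; returns (dsb_records, ssb_breaks).

    Expects adjacent-merged breaks (conversion applied upstream).  DSB
    records carry the representative position (floor of the pair
    midpoint), member positions, origins and the track of the
    plus-strand member.
    """
    if len(breaks) == 0:
        return _empty_dsb(), breaks.copy()
    df = breaks.sort_values(["chromosome", "pos", "strand"],
                            kind="stable").reset_index(drop=True)
    dsb_rows = []
    ssb_idx = []
    for chrom, sub in df.groupby("chromosome", sort=False):
        pos = sub["pos"].to_numpy()
        strand = sub["strand"].to_numpy()
        idx = sub.index.to_numpy()
        used = np.zeros(len(sub), dtype=bool)
        for i in range(len(sub)):
            if used[i]:
                continue
            # nearest unpaired opposite-strand break within 10 bp
            best = -1
            best_key = None
            for j in range(len(sub)):
                if used[j] or j == i or strand[j] == strand[i]:
                    continue
                d = abs(int(pos[j]) - int(pos[i]))
                if d > DSB_MAX_BP:
                    continue
                key = (d, int(pos[j]), int(strand[j]))
                if best_key is None or key < best_key:
                    best, best_key = j, key
            if best >= 0:
                used[i] = used[best] = True
                pi, pj = int(pos[i]), int(pos[best])
                plus = i if strand[i] == 0 else best
                dsb_rows.append({
                    "chromosome": chrom,
                    "pos": (pi + pj) // 2,
                    "pos_plus": int(pos[plus]),
                    "pos_minus": int(pos[i if plus != i else best]),
                    "origin_pair": "|".join(sorted(
                        (df.at[idx[i], "origin"], df.at[idx[best], "origin"]))),
                    "track_id": int(df.at[idx[plus], "track_id"]),
                })
        ssb_idx.extend(idx[~used])
    dsb = pd.DataFrame(dsb_rows) if dsb_rows else _empty_dsb()
    if len(dsb):
        dsb = dsb.sort_values(["chromosome", "pos"],
                              kind="stable").reset_index(drop=True)
    ssb = df.loc[sorted(ssb_idx)].reset_index(drop=True)
    return dsb, ssb


def _empty_dsb() -> pd.DataFrame:
    return pd.DataFrame({
        "chromosome": pd.Series(dtype=np.int64),
        "pos": pd.Series(dtype=np.int64),
        "pos_plus": pd.Series(dtype=np.int64),
        "pos_minus": pd.Series(dtype=np.int64),
        "origin_pair": pd.Series(dtype=object),
        "track_id": pd.Series(dtype=np.int64),
    })


def cluster_dsb(dsb: pd.DataFrame) -> pd.DataFrame:
    """Single-linkage chaining of DSB representative positions (<=25 bp).

    Returns one row per cluster-or-isolated-DSB (i.e. per DSB *site*)
    with the member count (multiplicity), representative position (mean
    of member positions), genomic extent, micro-fragment count
    (multiplicity - 1) and the track of the first member.
    """
    if len(dsb) == 0:
        return pd.DataFrame({
            "chromosome": pd.Series(dtype=np.int64),
            "pos": pd.Series(dtype=float),
            "pos_lo": pd.Series(dtype=np.int64),
            "pos_hi": pd.Series(dtype=np.int64),
            "multiplicity": pd.Series(dtype=np.int64),
            "is_cluster": pd.Series(dtype=bool),
            "micro_fragments": pd.Series(dtype=np.int64),
            "track_id": pd.Series(dtype=np.int64),
        })
    df = dsb.sort_values(["chromosome", "pos"],
                         kind="stable").reset_index(drop=True)
    chrom = df["chromosome"].to_numpy()
    pos = df["pos"].to_numpy()
    new_grp = np.empty(len(df), dtype=bool)
    new_grp[0] = True
    new_grp[1:] = (chrom[1:] != chrom[:-1]) | (pos[1:] - pos[:-1] > CLUSTER_MAX_BP)
    grp = np.cumsum(new_grp) - 1
    out = df.assign(_grp=grp).groupby("_grp", sort=True).agg(
        chromosome=("chromosome", "first"),
        pos=("pos", "mean"),
        pos_lo=("pos", "min"),
        pos_hi=("pos", "max"),
        multiplicity=("pos", "size"),
        track_id=("track_id", "first"),
    ).reset_index(drop=True)
    out["is_cluster"] = out["multiplicity"] >= 2
    out["micro_fragments"] = out["multiplicity"] - 1
    return out


@dataclass
class DamageSummary:
    """Damage tallies of one exposure (absolute counts).

    Invariants: ``sb == ssb + 2 * dsb``;
    ``dsb == isolated_dsb + clustered_dsb``;
    ``dsb_sites == isolated_dsb + dsb_clusters``.
    """

    sb: int
    ssb: int
    dsb: int
    isolated_dsb: int
    dsb_clusters: int
    dsb_sites: int
    clustered_dsb: int
    multiplicity: float          # mean DSB per cluster (nan if no cluster)
    micro_fragments: int
    fragment_counts: dict = field(default_factory=dict)
    dose_gy: float = float("nan")
    genome_gbp: float = float("nan")

    def per_gy_per_gbp(self, count: float) -> float:
        """Normalize an absolute count to Gy^-1 Gbp^-1."""
        if not np.isfinite(self.dose_gy) or self.dose_gy <= 0:
            raise ValueError("per-Gy normalization needs a positive dose")
        return count / (self.dose_gy * self.genome_gbp)

    def yields_per_gy_gbp(self) -> dict:
        keys = ["sb", "ssb", "dsb", "isolated_dsb", "dsb_clusters",
                "dsb_sites"]
        return {k: self.per_gy_per_gbp(getattr(self, k)) for k in keys}


def summarize(sites: pd.DataFrame, ssb: pd.DataFrame,
              dose_gy: float = float("nan"),
              genome_length_bp: float = float("nan"),
              fragment_counts: dict | None = None) -> DamageSummary:
    """Aggregate site/SSB tables into a :class:`DamageSummary`."""
    n_ssb = len(ssb)
    mult = sites["multiplicity"].to_numpy() if len(sites) else np.empty(0)
    n_dsb = int(mult.sum())
    is_cluster = sites["is_cluster"].to_numpy() if len(sites) else np.empty(0, bool)
    n_clusters = int(is_cluster.sum())
    n_isolated = int((~is_cluster).sum())
    clustered = int(mult[is_cluster].sum()) if n_clusters else 0
    return DamageSummary(
        sb=n_ssb + 2 * n_dsb,
        ssb=n_ssb,
        dsb=n_dsb,
        isolated_dsb=n_isolated,
        dsb_clusters=n_clusters,
        dsb_sites=n_isolated + n_clusters,
        clustered_dsb=clustered,
        multiplicity=clustered / n_clusters if n_clusters else float("nan"),
        micro_fragments=int((mult[is_cluster] - 1).sum()) if n_clusters else 0,
        fragment_counts=fragment_counts or {},
        dose_gy=dose_gy,
        genome_gbp=genome_length_bp / 1e9,
    )


def fragment_spectrum(sites: pd.DataFrame,
                      bins=DEFAULT_FRAGMENT_BINS,
                      include_pfge: bool = True) -> dict:
    """Single-track DNA fragment counts per size bin.

    Fragment lengths are gaps between consecutive DSB-site
    representative positions of the same track on the same chromosome;
    end pieces (chromosome end to first/last site) are not counted.
    """
    labels = [b[0] for b in bins] + ([PFGE_BIN[0]] if include_pfge else [])
    counts = {label: 0 for label in labels}
    if len(sites) == 0:
        return counts
    df = sites.sort_values(["track_id", "chromosome", "pos"], kind="stable")
    track = df["track_id"].to_numpy()
    chrom = df["chromosome"].to_numpy()
    pos = df["pos"].to_numpy(dtype=float)
    same = (track[1:] == track[:-1]) & (chrom[1:] == chrom[:-1])
    gaps = (pos[1:] - pos[:-1])[same]
    all_bins = list(bins) + ([PFGE_BIN] if include_pfge else [])
    for label, lo, hi in all_bins:
        counts[label] = int(np.count_nonzero((gaps >= lo) & (gaps <= hi)))
    return counts


def classify_breaks(breaks: pd.DataFrame,
                    dose_gy: float = float("nan"),
                    genome_length_bp: float = float("nan"),
                    fragment_bins=DEFAULT_FRAGMENT_BINS):
    """Run the full classification chain on a break list.

    Returns ``(summary, sites, dsb, ssb)``.  Expects SB->DSB conversion
    (when wanted) already applied to the break list.
    """
    merged = merge_adjacent(breaks)
    dsb, ssb = call_dsb(merged)
    sites = cluster_dsb(dsb)
    frags = fragment_spectrum(sites, fragment_bins)
    summary = summarize(sites, ssb, dose_gy, genome_length_bp, frags)
    return summary, sites, dsb, ssb
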