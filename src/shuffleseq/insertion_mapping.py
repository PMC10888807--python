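"""Map cassette integration sites from T7 IVT read observations.

The mapper reconstructs, for every integrated cassette: chromosome, the
1-based position of the left TTAA duplication, cassette orientation
(top-CS2 / bottom-CS1), haplotype allele, and the barcode pair — using only
the geometry of piggyBac target-site duplication. Reads from the two T7
sides of one insertion align to opposite genome strands; with BED-style
junction coordinates (minus-strand cluster at its 0-based start,
plus-strand cluster at its 1-based end) the two clusters of a genuine
insertion sit exactly 4 bp apart, minus-strand cluster first, with
reverse-complementary barcodes and opposite cassette strands.

Observations are consumed as a documented tabular format
(:data:`OBS_COLUMNS`); :class:`ReadPlacer` produces that table from
simulator FASTQ-style reads against the synthetic genome.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np
import pandas as pd

from .simulate import (TOP, BOTTOM, CassetteDesign, DEFAULT_DESIGN,
                       GenomeModel, revcomp)

OBS_COLUMNS = ["read_id", "bc_first", "bc_second", "cassette_strand",
               "chrom", "align_start", "align_end", "genome_strand",
               "read1_umi", "read2_umi", "allele_call", "multimapped",
               "junction_is_ttaa"]

CLUSTER_COLUMNS = ["cluster_id", "chrom", "position", "genome_strand",
                   "cassette_strand", "bc_first", "bc_second", "allele",
                   "read_count", "umi1_count", "umi2_count",
                   "n_unique_lengths"]

NO_VARIANT = "noVariant"
INCONCLUSIVE = "inconclusive"


def levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def joint_barcode_distance(pair_a: tuple[str, str], pair_b: tuple[str, str]) -> int:
    """Summed per-barcode Levenshtein distance, one budget for the pair."""
    return (levenshtein(pair_a[0], pair_b[0])
            + levenshtein(pair_a[1], pair_b[1]))


# --------------------------------------------------------------------------
# barcode extraction from read 1
# --------------------------------------------------------------------------

_RE_CACHE: dict[tuple[str, int], re.Pattern] = {}


def _anchored(anchor: str, n: int) -> re.Pattern:
    key = (anchor, n)
    if key not in _RE_CACHE:
        _RE_CACHE[key] = re.compile(anchor + "([ACGT]{%d})" % n)
    return _RE_CACHE[key]


def extract_barcodes(read1: str, design: CassetteDesign = DEFAULT_DESIGN
                     ) -> tuple[str, str, str] | None:
    """Extract (cassette_strand, bc_first, bc_second) from a barcode read.

    Anchors are matched exactly: ``TGAGC(.{20})ATAAC`` then ``GTTAT(.{20})``
    for the top-CS2 frame, ``AAAGC(.{20})ATAAC`` then ``GTTAT(.{20})`` for
    the bottom-CS1 frame. Returns None if no frame matches.
    """
    n1, n2 = design.bc1_length, design.bc2_length
    for frame, first_anchor in ((TOP, "TGAGC"), (BOTTOM, "AAAGC")):
        m1 = _anchored(first_anchor, n1).search(read1)
        if m1 is None or read1[m1.end():m1.end() + 5] != "ATAAC":
            continue
        m2 = _anchored("GTTAT", n2).search(read1, m1.end())
        if m2 is None:
            continue
        return frame, m1.group(1), m2.group(1)
    return None


# --------------------------------------------------------------------------
# synthetic-genome read placement
# --------------------------------------------------------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


class ReadPlacer:
    """Seed-and-verify placement of flank reads on the synthetic genome.

    Alignment is against the first (reference) haplotype; reads from the
    other haplotype place with a small number of mismatches at variant
    positions, which downstream allele calling interprets. A read is
    multimapped if more than one genomic location verifies within the
    mismatch allowance. This is deliberately a naive placer for synthetic
    genomes, not a general-purpose aligner.
    """

    def __init__(self, genome: GenomeModel, seed_len: int = 16,
                 max_mismatch_frac: float = 0.06, min_mismatch_allow: int = 5):
        self.genome = genome
        self.seed_len = seed_len
        self.max_mismatch_frac = max_mismatch_frac
        self.min_mismatch_allow = min_mismatch_allow
        self.ref_hap = genome.haplotypes[0]
        chroms = genome.chrom_names()
        parts = [_encode(genome.sequence[self.ref_hap][c]) for c in chroms]
        self._offsets = np.cumsum([0] + [p.size for p in parts])
        self._chroms = chroms
        self._arr = np.concatenate(parts)
        k = seed_len
        n = self._arr.size - k + 1
        kmers = self._arr[:n].astype(np.uint64)
        for j in range(1, k):
            kmers = kmers * 4 + self._arr[j:j + n]
        # invalidate k-mers spanning chromosome boundaries
        valid = np.ones(n, dtype=bool)
        for off in self._offsets[1:-1]:
            valid[max(0, off - k + 1):off] = False
        order = np.argsort(kmers, kind="stable")
        self._sorted_kmers = kmers[order]
        self._sorted_pos = order.astype(np.int64)
        self._valid = valid
        # per-chromosome variant lookup for allele calls
        self._variants: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        v = genome.variants
        for c in chroms:
            sub = v[v["chrom"] == c]
            self._variants[c] = (
                sub["pos"].to_numpy(np.int64),
                _encode("".join(sub["ref"])) if len(sub) else np.empty(0, np.uint8),
                _encode("".join(sub["alt"])) if len(sub) else np.empty(0, np.uint8),
            )

    def _locate(self, g: int) -> tuple[str, int]:
        ci = int(np.searchsorted(self._offsets, g, side="right")) - 1
        return self._chroms[ci], g - int(self._offsets[ci])

    def _seed_hits(self, q: np.ndarray) -> set[int]:
        k = self.seed_len
        hits: set[int] = set()
        offsets = [0, k + 1, 2 * (k + 1)]
        for off in offsets:
            if off + k > q.size:
                break
            v = np.uint64(0)
            for j in range(k):
                v = v * np.uint64(4) + np.uint64(q[off + j])
            lo = int(np.searchsorted(self._sorted_kmers, v, side="left"))
            hi = int(np.searchsorted(self._sorted_kmers, v, side="right"))
            for p in self._sorted_pos[lo:hi]:
                start = int(p) - off
                if start >= 0 and self._valid[min(int(p), self._valid.size - 1)]:
                    hits.add(start)
        return hits

    def place(self, read2: str) -> dict | None:
        """Place one flank read; returns alignment fields or None."""
        allow = max(self.min_mismatch_allow,
                    int(len(read2) * self.max_mismatch_frac))
        candidates: list[tuple[int, str, int]] = []
        for strand, seq in (("+", read2), ("-", revcomp(read2))):
            q = _encode(seq)
            if np.any(q == 255):
                continue
            for start in self._seed_hits(q):
                end = start + q.size
                if end > self._arr.size:
                    continue
                mm = int(np.count_nonzero(self._arr[start:end] != q))
                if mm <= allow:
                    candidates.append((start, strand, mm))
        if not candidates:
            return None
        candidates.sort(key=lambda c: (c[2], c[0], c[1]))
        start, strand, _mm = candidates[0]
        # distinct genomic spans -> multimapped
        multi = len({(c[0], c[1]) for c in candidates}) > 1
        chrom, local = self._locate(start)
        # the chosen span must not cross a chromosome boundary
        if local + len(read2) > dict(self.genome.chromosomes)[chrom]:
            return None
        align_start = local + 1                     # 1-based inclusive
        align_end = local + len(read2)
        q = _encode(read2 if strand == "+" else revcomp(read2))
        allele = self._call_allele(chrom, align_start, align_end, q)
        junction = self._junction_is_ttaa(chrom, align_start, align_end, strand)
        return {
            "chrom": chrom, "align_start": align_start, "align_end": align_end,
            "genome_strand": strand, "allele_call": allele,
            "multimapped": multi, "junction_is_ttaa": junction,
        }

    def _call_allele(self, chrom: str, start: int, end: int,
                     q: np.ndarray) -> str:
        pos, ref, alt = self._variants[chrom]
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end, side="right"))
        if hi <= lo:
            return NO_VARIANT
        calls = set()
        for i in range(lo, hi):
            base = q[pos[i] - start]
            if base == ref[i]:
                calls.add(self.genome.haplotypes[0])
            elif base == alt[i]:
                calls.add(self.genome.haplotypes[1])
        if len(calls) == 1:
            return calls.pop()
        if len(calls) == 0:
            return NO_VARIANT  # sequencing error at every variant base
        return INCONCLUSIVE

    def _junction_is_ttaa(self, chrom: str, start: int, end: int,
                          strand: str) -> bool:
        seq = self.genome.sequence[self.ref_hap][chrom]
        if strand == "+":
            return seq[end - 4:end] == "TTAA"
        return seq[start - 1:start + 3] == "TTAA"


def observations_from_reads(reads: pd.DataFrame, genome: GenomeModel,
                            design: CassetteDesign = DEFAULT_DESIGN,
                            placer: ReadPlacer | None = None
                            ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Extract barcodes from read 1 and place read 2; tally drop reasons."""
    placer = placer or ReadPlacer(genome)
    rows: list[tuple] = []
    drops: Counter = Counter()
    for r in reads.itertuples(index=False):
        ext = extract_barcodes(r.read1, design)
        if ext is None:
            drops["no_anchor_match"] += 1
            continue
        frame, b1, b2 = ext
        aln = placer.place(r.read2)
        if aln is None:
            drops["unaligned"] += 1
            continue
        rows.append((r.read_id, b1, b2, frame, aln["chrom"],
                     aln["align_start"], aln["align_end"],
                     aln["genome_strand"], r.read1_umi, r.read2[:8],
                     aln["allele_call"], aln["multimapped"],
                     aln["junction_is_ttaa"]))
    return pd.DataFrame(rows, columns=OBS_COLUMNS), dict(drops)


# --------------------------------------------------------------------------
# alignment filtering and the position rule
# --------------------------------------------------------------------------

def filter_alignment(obs: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep uniquely mapped reads whose junction lands on a TTAA.

    Reads with an inconclusive within-read allele call are also discarded.
    """
    drops = {
        "multimapped": int(obs["multimapped"].sum()),
        "junction_not_ttaa": int((~obs["junction_is_ttaa"]).sum()),
        "inconclusive_allele": int((obs["allele_call"] == INCONCLUSIVE).sum()),
    }
    keep = (~obs["multimapped"] & obs["junction_is_ttaa"]
            & (obs["allele_call"] != INCONCLUSIVE))
    return obs[keep].reset_index(drop=True), drops


def junction_position(align_start: int, align_end: int, genome_strand: str) -> int:
    """BED-convention junction coordinate of one alignment.

    Plus-strand reads end at the junction (1-based inclusive end == BED
    end); minus-strand reads start at it (BED start == 1-based start − 1).
    The two clusters of one insertion then differ by exactly 4 bp — the
    length of the duplicated TTAA.
    """
    return align_end if genome_strand == "+" else align_start - 1


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------

def _modal(values: Sequence[str]) -> str:
    counts = Counter(values)
    top = max(counts.values())
    return min(v for v, c in counts.items() if c == top)


def _cluster_allele(values: Sequence[str]) -> str:
    counts = Counter(v for v in values if v != NO_VARIANT)
    if not counts:
        return NO_VARIANT
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return INCONCLUSIVE
    return ranked[0][0]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_observations(obs: pd.DataFrame,
                         levenshtein_budget: int = 6) -> pd.DataFrame:
    """Single-linkage clustering of observations at each junction position.

    Observations sharing (chrom, position) are linked when their joint
    barcode distance (Levenshtein on each barcode, summed) is within the
    budget. Representative values are modal over members (ties broken by
    the lexicographically smallest value); the cluster allele is the
    majority ignoring noVariant members. Input order does not matter:
    members are canonically sorted before linkage.
    """
    if obs.empty:
        return pd.DataFrame(columns=CLUSTER_COLUMNS)
    obs = obs.copy()
    obs["position"] = [junction_position(s, e, st) for s, e, st in
                       zip(obs["align_start"], obs["align_end"],
                           obs["genome_strand"])]
    rows: list[tuple] = []
    cid = 0
    for (chrom, position), grp in obs.groupby(["chrom", "position"], sort=True):
        grp = grp.sort_values(["bc_first", "bc_second", "read_id"]).reset_index(drop=True)
        n = len(grp)
        uf = _UnionFind(n)
        pairs = list(zip(grp["bc_first"], grp["bc_second"]))
        for i in range(n):
            for j in range(i + 1, n):
                if uf.find(i) == uf.find(j):
                    continue
                if joint_barcode_distance(pairs[i], pairs[j]) <= levenshtein_budget:
                    uf.union(i, j)
        roots: dict[int, list[int]] = {}
        for i in range(n):
            roots.setdefault(uf.find(i), []).append(i)
        for root in sorted(roots):
            members = grp.iloc[roots[root]]
            rows.append((
                f"cl{cid:07d}", chrom, position,
                _modal(members["genome_strand"]),
                _modal(members["cassette_strand"]),
                _modal(members["bc_first"]), _modal(members["bc_second"]),
                _cluster_allele(members["allele_call"]),
                len(members),
                members["read1_umi"].nunique(),
                members["read2_umi"].nunique(),
                (members["align_end"] - members["align_start"]).nunique(),
            ))
            cid += 1
    return pd.DataFrame(rows, columns=CLUSTER_COLUMNS)


# --------------------------------------------------------------------------
# replicate merging
# --------------------------------------------------------------------------

_MERGE_KEY = ["chrom", "position", "genome_strand", "cassette_strand",
              "bc_first", "bc_second"]


def _reconcile_alleles(alleles: Sequence[str]) -> str:
    informative = {a for a in alleles if a not in (NO_VARIANT,)}
    if INCONCLUSIVE in informative:
        return INCONCLUSIVE
    if len(informative) > 1:
        return INCONCLUSIVE
    if len(informative) == 1:
        return informative.pop()
    return NO_VARIANT


def merge_replicates(cluster_tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Intersect clusters across replicates on position/barcode/strand keys.

    Per-replicate support columns are suffixed ``_r1, _r2, …``; the merged
    allele is the replicates' reconciliation (incongruent → inconclusive).
    """
    merged: pd.DataFrame | None = None
    for i, tab in enumerate(cluster_tables, start=1):
        t = tab.drop(columns=["cluster_id"]).rename(columns={
            c: f"{c}_r{i}" for c in
            ("allele", "read_count", "umi1_count", "umi2_count",
             "n_unique_lengths")})
        merged = t if merged is None else merged.merge(t, on=_MERGE_KEY, how="inner")
    if merged is None:
        raise ValueError("need at least one replicate")
    n = len(cluster_tables)
    allele_cols = [f"allele_r{i}" for i in range(1, n + 1)]
    merged["allele"] = [_reconcile_alleles(vals) for vals in
                        merged[allele_cols].itertuples(index=False)]
    merged["read_count"] = merged[[f"read_count_r{i}" for i in range(1, n + 1)]].sum(axis=1)
    merged = merged.sort_values(_MERGE_KEY).reset_index(drop=True)
    merged.insert(0, "cluster_id", [f"mg{i:07d}" for i in range(len(merged))])
    return merged


# --------------------------------------------------------------------------
# cluster-level filters
# --------------------------------------------------------------------------

def filter_cluster_support(merged: pd.DataFrame, min_reads: int = 6,
                           min_unique_lengths: int = 3,
                           support_replicate: int = 2) -> pd.DataFrame:
    """Remove clusters with < min_reads reads AND < min lengths (literal
    conjunction) in the support replicate; falls back to the last available
    replicate when fewer are present."""
    rep = support_replicate
    while f"read_count_r{rep}" not in merged.columns and rep > 1:
        rep -= 1
    reads = merged[f"read_count_r{rep}"]
    lengths = merged[f"n_unique_lengths_r{rep}"]
    drop = (reads < min_reads) & (lengths < min_unique_lengths)
    return merged[~drop].reset_index(drop=True)


def filter_unique_mapping(clusters: pd.DataFrame) -> pd.DataFrame:
    """Drop clusters whose barcode pair occurs at more than one position."""
    if clusters.empty:
        return clusters
    sites = clusters[["bc_first", "bc_second", "chrom", "position"]].drop_duplicates()
    counts = sites.groupby(["bc_first", "bc_second"]).size()
    multi = set(counts[counts > 1].index)
    keep = [
        (b1, b2) not in multi
        for b1, b2 in zip(clusters["bc_first"], clusters["bc_second"])
    ]
    return clusters[keep].reset_index(drop=True)


# --------------------------------------------------------------------------
# cluster pairing -> candidate insertions
# --------------------------------------------------------------------------

CANDIDATE_COLUMNS = ["chrom", "pos", "orientation", "allele", "bc1", "bc2",
                     "read_count_minus", "read_count_plus",
                     "lengths_minus", "lengths_plus"]


def assign_insertion_allele(allele_minus: str, allele_plus: str) -> str:
    """Reconcile the two paired clusters' alleles into the insertion allele."""
    a, b = allele_minus, allele_plus
    if INCONCLUSIVE in (a, b):
        return INCONCLUSIVE
    if a == NO_VARIANT and b == NO_VARIANT:
        return INCONCLUSIVE
    if a == NO_VARIANT:
        return b
    if b == NO_VARIANT:
        return a
    return a if a == b else INCONCLUSIVE


def pair_clusters(clusters: pd.DataFrame, offset: int = 4,
                  support_replicate: int = 2
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair (−,+) clusters exactly ``offset`` bp apart into insertions.

    A pair qualifies iff the minus-strand cluster comes first, the two
    clusters' cassette strands differ, and their barcodes are mutual
    reverse complements. The insertion position is the 1-based first base
    of the left TTAA (minus-cluster BED position + 1); orientation is the
    minus cluster's cassette strand. Returns (candidates, unpaired).
    """
    rep = support_replicate
    len_col = f"n_unique_lengths_r{rep}"
    if len_col not in clusters.columns:
        len_col = ("n_unique_lengths" if "n_unique_lengths" in clusters.columns
                   else "n_unique_lengths_r1")
    minus = clusters[clusters["genome_strand"] == "-"]
    plus = clusters[clusters["genome_strand"] == "+"]
    plus_ix: dict[tuple[str, int], list[int]] = {}
    for i, row in plus.iterrows():
        plus_ix.setdefault((row["chrom"], row["position"]), []).append(i)
    rows: list[tuple] = []
    paired_ids: set[str] = set()
    for _, m in minus.iterrows():
        for j in plus_ix.get((m["chrom"], m["position"] + offset), []):
            p = plus.loc[j]
            if m["cassette_strand"] == p["cassette_strand"]:
                continue
            if (m["bc_first"] != revcomp(p["bc_second"])
                    or m["bc_second"] != revcomp(p["bc_first"])):
                continue
            orientation = m["cassette_strand"]
            if orientation == TOP:
                bc1, bc2 = m["bc_first"], m["bc_second"]
            else:
                bc1, bc2 = revcomp(m["bc_second"]), revcomp(m["bc_first"])
            rows.append((
                m["chrom"], m["position"] + 1, orientation,
                assign_insertion_allele(m["allele"], p["allele"]),
                bc1, bc2,
                m["read_count"], p["read_count"],
                m[len_col], p[len_col],
            ))
            paired_ids.update([m["cluster_id"], p["cluster_id"]])
    candidates = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    unpaired = clusters[~clusters["cluster_id"].isin(paired_ids)].reset_index(drop=True)
    return candidates.sort_values(["chrom", "pos"]).reset_index(drop=True), unpaired


# --------------------------------------------------------------------------
# final insertion filters
# --------------------------------------------------------------------------

def filter_amplicon_support(candidates: pd.DataFrame,
                            support: pd.DataFrame,
                            min_reads: float = 50.0,
                            min_umis: float = 30.0) -> pd.DataFrame:
    """Keep candidates whose barcode pair exceeds both amplicon thresholds.

    ``support`` has columns bc1, bc2, mean_reads, mean_umis — depth-scaled
    counts averaged over parental amplicon replicates. Thresholds are
    exclusive (> min_reads and > min_umis).
    """
    sup = support.set_index(["bc1", "bc2"])
    keep = []
    for b1, b2 in zip(candidates["bc1"], candidates["bc2"]):
        if (b1, b2) in sup.index:
            row = sup.loc[(b1, b2)]
            keep.append(bool(row["mean_reads"] > min_reads
                             and row["mean_umis"] > min_umis))
        else:
            keep.append(False)
    return candidates[keep].reset_index(drop=True)


def resolve_multi_pair_sites(candidates: pd.DataFrame) -> pd.DataFrame:
    """Where one site has several candidate pairs, keep the one whose
    minus-side cluster aligned with more unique lengths (ties: smallest
    bc1, for determinism)."""
    out = (candidates
           .sort_values(["chrom", "pos", "lengths_minus", "bc1"],
                        ascending=[True, True, False, True])
           .drop_duplicates(["chrom", "pos"], keep="first"))
    return out.reset_index(drop=True)


def filter_bonafide_insertions(candidates: pd.DataFrame,
                               amplicon_support: pd.DataFrame | None,
                               min_reads: float = 50.0,
                               min_umis: float = 30.0) -> pd.DataFrame:
    """Apply the amplicon-support and multi-pair-site filters to candidates."""
    out = candidates
    if amplicon_support is not None:
        out = filter_amplicon_support(out, amplicon_support, min_reads, min_umis)
    return resolve_multi_pair_sites(out)


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

@dataclass
class MappingResult:
    insertions: pd.DataFrame
    candidates: pd.DataFrame
    merged_clusters: pd.DataFrame
    unpaired: pd.DataFrame
    per_replicate_clusters: list[pd.DataFrame]
    report: dict[str, int] = field(default_factory=dict)


def map_insertions(obs_replicates: Sequence[pd.DataFrame], config,
                   amplicon_support: pd.DataFrame | None = None
                   ) -> MappingResult:
    """Full insertion-mapping pipeline over N ≥ 1 observation replicates."""
    report: dict[str, int] = {}
    per_rep: list[pd.DataFrame] = []
    for i, obs in enumerate(obs_replicates, start=1):
        kept, drops = filter_alignment(obs)
        for reason, nd in drops.items():
            report[f"r{i}_{reason}"] = nd
        report[f"r{i}_observations"] = len(kept)
        clusters = cluster_observations(kept, config.levenshtein_budget)
        report[f"r{i}_clusters"] = len(clusters)
        per_rep.append(clusters)
    merged = merge_replicates(per_rep)
    report["merged_clusters"] = len(merged)
    merged = filter_cluster_support(merged, config.min_cluster_reads,
                                    config.min_unique_lengths,
                                    config.support_replicate)
    report["after_support_filter"] = len(merged)
    merged = filter_unique_mapping(merged)
    report["after_unique_mapping"] = len(merged)
    candidates, unpaired = pair_clusters(merged, config.cluster_pair_offset,
                                         config.support_replicate)
    report["candidate_insertions"] = len(candidates)
    report["unpaired_clusters"] = len(unpaired)
    insertions = filter_bonafide_insertions(
        candidates, amplicon_support,
        config.parental_min_reads, config.parental_min_umis)
    report["bonafide_insertions"] = len(insertions)
    return MappingResult(insertions, candidates, merged, unpaired, per_rep,
                         report)


def cluster_canonical_pairs(clusters: pd.DataFrame) -> set[tuple[str, str]]:
    """Canonical (bc1, bc2) pairs carried by a cluster table.

    Top-CS2-frame clusters store (bc1, bc2) directly; bottom-CS1-frame
    clusters store (rc(bc2), rc(bc1)).
    """
    pairs: set[tuple[str, str]] = set()
    for frame, b1, b2 in zip(clusters["cassette_strand"],
                             clusters["bc_first"], clusters["bc_second"]):
        if frame == TOP:
            pairs.add((b1, b2))
        else:
            pairs.add((revcomp(b2), revcomp(b1)))
    return pairs
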