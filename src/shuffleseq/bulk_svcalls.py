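"""Call structural variants from bulk amplicon barcode-pair counts.

A rearranged cassette is visible as a *novel* barcode pair: both barcodes
belong to the bonafide parental insertion list but were never seen together
in parental cells. The class of the variant follows from the genomic
coordinates and orientations of the two parental insertions; deletions are
further split into the genomic-scar and ecDNA (excised circle) products by
which barcode of each insertion ended up in the pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .insertion_mapping import cluster_canonical_pairs, levenshtein
from .simulate import TOP

PAIR_COUNT_COLUMNS = ["bc1", "bc2", "read_count", "umi_count"]

REARRANGEMENT_COLUMNS = [
    "bc1", "bc2", "sv_class", "topology", "size",
    "ins_a", "chrom_a", "pos_a", "orientation_a", "allele_a",
    "ins_b", "chrom_b", "pos_b", "orientation_b", "allele_b",
    "inter_homolog", "read_count", "umi_count",
]


# --------------------------------------------------------------------------
# counting
# --------------------------------------------------------------------------

def count_amplicon_pairs(reads: pd.DataFrame,
                         dialect: str = "2-primer") -> pd.DataFrame:
    """Read and unique-UMI counts per barcode pair (and amplicon type)."""
    if reads.empty:
        cols = PAIR_COUNT_COLUMNS + (["amplicon_type"] if dialect == "4-primer" else [])
        return pd.DataFrame(columns=cols)
    keys = ["bc1", "bc2"] + (["amplicon_type"] if dialect == "4-primer" else [])
    out = (reads.groupby(keys)
           .agg(read_count=("umi", "size"), umi_count=("umi", "nunique"))
           .reset_index())
    return out.sort_values(keys).reset_index(drop=True)


def collapse_four_primer(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum the two amplicon types per cassette; drop pairs missing one type."""
    if "amplicon_type" not in counts.columns:
        return counts.copy()
    if counts.empty:
        return pd.DataFrame(columns=PAIR_COUNT_COLUMNS)
    g = counts.groupby(["bc1", "bc2"])
    out = g.agg(read_count=("read_count", "sum"),
                umi_count=("umi_count", "sum"),
                n_types=("amplicon_type", "nunique")).reset_index()
    out = out[out["n_types"] == 2].drop(columns="n_types")
    return out.reset_index(drop=True)


def normalize_counts(counts: pd.DataFrame, scale: float = 1e6) -> pd.DataFrame:
    """Depth-normalize read/UMI counts (counts per ``scale``, default CPM)."""
    out = counts.copy()
    total_reads = out["read_count"].sum()
    total_umis = out["umi_count"].sum()
    out["normalized_read_count"] = (
        out["read_count"] * scale / total_reads if total_reads else 0.0)
    out["normalized_umi_count"] = (
        out["umi_count"] * scale / total_umis if total_umis else 0.0)
    return out


def average_parental_replicates(replicates: list[pd.DataFrame],
                                scale: float = 1e6) -> pd.DataFrame:
    """Average depth-normalized counts over parental amplicon replicates.

    The result is rescaled back to the mean per-replicate depth so that the
    bonafide-insertion thresholds (>50 reads, >30 UMIs) keep their
    read-count units. Pairs absent from a replicate count as zero.
    """
    normed = [normalize_counts(r, scale) for r in replicates]
    all_pairs = pd.concat([n[["bc1", "bc2"]] for n in normed]).drop_duplicates()
    acc = all_pairs.set_index(["bc1", "bc2"])
    reads = np.zeros(len(acc))
    umis = np.zeros(len(acc))
    for n in normed:
        ni = n.set_index(["bc1", "bc2"])
        reads += ni["normalized_read_count"].reindex(acc.index, fill_value=0.0).to_numpy()
        umis += ni["normalized_umi_count"].reindex(acc.index, fill_value=0.0).to_numpy()
    k = len(normed)
    mean_read_depth = np.mean([r["read_count"].sum() for r in replicates])
    mean_umi_depth = np.mean([r["umi_count"].sum() for r in replicates])
    out = acc.reset_index()
    out["mean_reads"] = reads / k * mean_read_depth / scale
    out["mean_umis"] = umis / k * mean_umi_depth / scale
    return out


def derive_well_barcode_set(per_well_counts: pd.DataFrame,
                            well_min_reads: int = 100_000
                            ) -> dict[str, set[tuple[str, str]]]:
    """Barcode pairs per clone well: read count > mean + 1 population SD.

    ``per_well_counts`` needs columns well_id, bc1, bc2, read_count. Wells
    whose total reads fall below ``well_min_reads`` are discarded.
    """
    out: dict[str, set[tuple[str, str]]] = {}
    for well, grp in per_well_counts.groupby("well_id"):
        if grp["read_count"].sum() < well_min_reads:
            continue
        vals = grp["read_count"].to_numpy(float)
        cut = vals.mean() + vals.std(ddof=0)
        keep = grp[grp["read_count"] > cut]
        out[str(well)] = set(zip(keep["bc1"], keep["bc2"]))
    return out


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

def classify_sv(ins_a: pd.Series, ins_b: pd.Series) -> tuple[str, int]:
    """(class, size) from the two parental insertions of a novel pair.

    Same chromosome + same orientation → deletion; same chromosome +
    opposite orientation → inversion; different chromosomes →
    translocation (size −1). Size is the distance between the two
    insertion positions.
    """
    if ins_a["chrom"] != ins_b["chrom"]:
        return "translocation", -1
    size = int(abs(int(ins_a["pos"]) - int(ins_b["pos"])))
    if ins_a["orientation"] == ins_b["orientation"]:
        return "deletion", size
    return "inversion", size


def classify_deletion_topology(ins_bc1_owner: pd.Series,
                               ins_bc2_owner: pd.Series) -> str:
    """Genomic scar vs ecDNA for a deletion-indicative novel pair.

    For two top-CS2 insertions X (left) and Y (right): the scarred
    chromosome keeps (BC1 of X, BC2 of Y) while the excised circle carries
    (BC1 of Y, BC2 of X). For two bottom-CS1 insertions the assignment is
    mirrored.
    """
    a, b = ins_bc1_owner, ins_bc2_owner  # a contributed its BC1, b its BC2
    left_is_a = (int(a["pos"]), a["insertion_id"]) <= (int(b["pos"]), b["insertion_id"])
    if a["orientation"] == TOP:
        return "genomic_scar" if left_is_a else "ecDNA"
    return "ecDNA" if left_is_a else "genomic_scar"


# --------------------------------------------------------------------------
# rearrangement calling
# --------------------------------------------------------------------------

@dataclass
class CallResult:
    calls: pd.DataFrame
    ambiguous: pd.DataFrame = field(default_factory=pd.DataFrame)
    unmatched: pd.DataFrame = field(default_factory=pd.DataFrame)


def _barcode_lookup(values: pd.Series) -> tuple[dict[str, int], set[str]]:
    lookup: dict[str, int] = {}
    ambiguous: set[str] = set()
    for i, v in enumerate(values):
        if v in lookup:
            ambiguous.add(v)
        else:
            lookup[v] = i
    return lookup, ambiguous


def call_rearrangements(sample_counts: pd.DataFrame,
                        bonafide: pd.DataFrame,
                        min_umi: int = 2,
                        match_mode: str = "exact",
                        levenshtein_budget: int = 6) -> CallResult:
    """Identify novel barcode pairs and classify the underlying SVs.

    ``bonafide`` needs columns insertion_id, chrom, pos, orientation,
    allele, bc1, bc2. A pair is called iff both barcodes are in the
    bonafide list, the pair itself is not parental, and its UMI support is
    ≥ ``min_umi``. Barcodes found in two or more insertions are reported as
    ambiguous, never called.
    """
    bona = bonafide.reset_index(drop=True)
    if "insertion_id" not in bona.columns:
        bona = bona.copy()
        bona["insertion_id"] = [f"bona{i:06d}" for i in range(len(bona))]
    bc1_lookup, amb1 = _barcode_lookup(bona["bc1"])
    bc2_lookup, amb2 = _barcode_lookup(bona["bc2"])
    parental = set(zip(bona["bc1"], bona["bc2"]))

    def resolve(bc: str, lookup: dict[str, int]) -> int | None:
        if bc in lookup:
            return lookup[bc]
        if match_mode == "levenshtein":
            hits = [i for v, i in lookup.items()
                    if levenshtein(bc, v) <= levenshtein_budget]
            if len(hits) == 1:
                return hits[0]
        return None

    rows: list[tuple] = []
    amb_rows: list[tuple] = []
    unmatched_rows: list[tuple] = []
    counts = sample_counts[sample_counts["umi_count"] >= min_umi]
    for rec in counts.itertuples(index=False):
        b1, b2 = rec.bc1, rec.bc2
        if b1 in amb1 or b2 in amb2:
            amb_rows.append((b1, b2, rec.read_count, rec.umi_count))
            continue
        ia = resolve(b1, bc1_lookup)
        ib = resolve(b2, bc2_lookup)
        if ia is None or ib is None:
            unmatched_rows.append((b1, b2, rec.read_count, rec.umi_count))
            continue
        a, b = bona.iloc[ia], bona.iloc[ib]
        if (a["bc1"], b["bc2"]) in parental and ia == ib:
            continue  # parental cassette
        if (b1, b2) in parental:
            continue
        sv_class, size = classify_sv(a, b)
        topology = "n/a"
        if sv_class == "deletion":
            topology = classify_deletion_topology(a, b)
        inter_homolog = bool(
            a["chrom"] == b["chrom"]
            and a["allele"] != b["allele"]
            and a["allele"] in ("BL6", "CAST") and b["allele"] in ("BL6", "CAST"))
        rows.append((b1, b2, sv_class, topology, size,
                     a["insertion_id"], a["chrom"], int(a["pos"]),
                     a["orientation"], a["allele"],
                     b["insertion_id"], b["chrom"], int(b["pos"]),
                     b["orientation"], b["allele"],
                     inter_homolog, rec.read_count, rec.umi_count))
    calls = pd.DataFrame(rows, columns=REARRANGEMENT_COLUMNS)
    aux_cols = ["bc1", "bc2", "read_count", "umi_count"]
    return CallResult(
        calls=calls.sort_values(["bc1", "bc2"]).reset_index(drop=True),
        ambiguous=pd.DataFrame(amb_rows, columns=aux_cols),
        unmatched=pd.DataFrame(unmatched_rows, columns=aux_cols),
    )


# --------------------------------------------------------------------------
# replicate intersection and IVT validation
# --------------------------------------------------------------------------

def intersect_replicates(calls_rep1: pd.DataFrame,
                         calls_rep2: pd.DataFrame) -> pd.DataFrame:
    """Union of the two replicates' calls with a ``replicated`` flag."""
    key = ["bc1", "bc2"]
    pairs1 = set(map(tuple, calls_rep1[key].to_numpy()))
    pairs2 = set(map(tuple, calls_rep2[key].to_numpy()))
    both = pairs1 & pairs2
    merged = (pd.concat([calls_rep1, calls_rep2])
              .drop_duplicates(key).reset_index(drop=True))
    merged["replicated"] = [tuple(p) in both
                            for p in merged[key].to_numpy()]
    return merged


def condition_sharing_fraction(replicated_a: pd.DataFrame,
                               replicated_b: pd.DataFrame) -> float:
    """Fraction of condition A's replicated calls also seen in condition B."""
    a = set(zip(replicated_a["bc1"], replicated_a["bc2"]))
    b = set(zip(replicated_b["bc1"], replicated_b["bc2"]))
    if not a:
        return float("nan")
    return len(a & b) / len(a)


def validate_with_ivt(calls: pd.DataFrame,
                      post_cre_clusters: pd.DataFrame,
                      parental_clusters: pd.DataFrame,
                      mode: str = "barcode") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag calls supported by post-Cre IVT transcripts.

    A call is supported iff at least one post-Cre IVT cluster carries the
    novel pair while the parental IVT data lacks it. ``mode="flank"``
    additionally requires the supporting cluster's junction to lie at one
    of the call's two parental insertion junctions (within the 4-bp
    duplication offset). Returns (calls with ``ivt_supported``,
    per-class supported fractions).
    """
    post_pairs = cluster_canonical_pairs(post_cre_clusters)
    parental_pairs = cluster_canonical_pairs(parental_clusters)
    flank_ix: dict[tuple[str, str], list[tuple[str, int]]] = {}
    if mode == "flank":
        from .insertion_mapping import TOP as _TOP  # local alias
        from .simulate import revcomp
        for row in post_cre_clusters.itertuples(index=False):
            pair = ((row.bc_first, row.bc_second)
                    if row.cassette_strand == _TOP
                    else (revcomp(row.bc_second), revcomp(row.bc_first)))
            flank_ix.setdefault(pair, []).append((row.chrom, row.position))
    supported = []
    for rec in calls.itertuples(index=False):
        pair = (rec.bc1, rec.bc2)
        ok = pair in post_pairs and pair not in parental_pairs
        if ok and mode == "flank":
            sites = flank_ix.get(pair, [])
            ok = any(
                (c == rec.chrom_a and abs(p - rec.pos_a) <= 4)
                or (c == rec.chrom_b and abs(p - rec.pos_b) <= 4)
                for c, p in sites)
        supported.append(bool(ok))
    out = calls.copy()
    out["ivt_supported"] = supported
    if len(out):
        frac = (out.groupby("sv_class")["ivt_supported"].mean()
                .rename("supported_fraction").reset_index())
    else:
        frac = pd.DataFrame(columns=["sv_class", "supported_fraction"])
    return out, frac


def class_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-class call counts and median sizes (cis classes only)."""
    if calls.empty:
        return pd.DataFrame(columns=["sv_class", "n_calls", "median_size"])
    rows = []
    for cls, grp in calls.groupby("sv_class"):
        sizes = grp.loc[grp["size"] >= 0, "size"]
        rows.append((cls, len(grp),
                     float(sizes.median()) if len(sizes) else float("nan")))
    return pd.DataFrame(rows, columns=["sv_class", "n_calls", "median_size"])
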