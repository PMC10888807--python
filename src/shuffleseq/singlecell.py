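"""Single-cell genotyping of rearrangements from T7 feature-barcode reads.

Pipeline: extract barcode pairs from captured T7 transcripts → discard
chimeric UMIs → collapse UMIs by Hamming-1 connected components → build the
barcode-pair-by-cell UMI matrix → reconstruct clonotypes (the full barcode
pair complement of each founder clone) de novo by community detection in a
PCA embedding → assign each cell to a clonotype by precision/recall → call
rearrangements that are congruent with the assigned clone (incongruent
novel pairs are flagged as probable ambient RNA).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .bulk_svcalls import CallResult, call_rearrangements
from .simulate import TOP, CassetteDesign, DEFAULT_DESIGN

T7_RECORD_COLUMNS = ["cell_bc", "umi", "bc1", "bc2", "capture_side",
                     "read_count"]


# --------------------------------------------------------------------------
# read extraction
# --------------------------------------------------------------------------

def extract_t7_record(read1: str, read2: str,
                      whitelist: set[str] | None = None,
                      design: CassetteDesign = DEFAULT_DESIGN,
                      cell_bc_len: int = 16, umi_len: int = 12,
                      window: tuple[int, int] = (10, 25)) -> dict | None:
    """Parse one 10x-layout read pair into a T7 record.

    Read 1 carries the 16-nt cell barcode + 12-nt UMI. Read 2 carries the
    captured transcript: CS2-side capture shows ``TGAGC(bc1)ATAAC`` then
    ``GTTAT(bc2)``; CS1-side capture shows ``AAAGC(bc2')ATAAC`` then
    ``GTTAT(bc1')`` with both barcodes reverse-complemented. The first
    anchor must start inside ``window`` (0-based, half-open slack around
    the expected offset 14). Cell barcodes are matched exactly against the
    whitelist when one is given.
    """
    from .insertion_mapping import extract_barcodes
    from .simulate import revcomp

    if len(read1) < cell_bc_len + umi_len:
        return None
    cell_bc = read1[:cell_bc_len]
    umi = read1[cell_bc_len:cell_bc_len + umi_len]
    if whitelist is not None and cell_bc not in whitelist:
        return None
    ext = extract_barcodes(read2, design)
    if ext is None:
        return None
    frame, b_first, b_second = ext
    anchor = "TGAGC" if frame == TOP else "AAAGC"
    start = read2.find(anchor)
    if not (window[0] <= start < window[1]):
        return None
    if frame == TOP:
        bc1, bc2, side = b_first, b_second, "CS2"
    else:
        bc1, bc2, side = revcomp(b_second), revcomp(b_first), "CS1"
    return {"cell_bc": cell_bc, "umi": umi, "bc1": bc1, "bc2": bc2,
            "capture_side": side, "read_count": 1}


# --------------------------------------------------------------------------
# chimeric-UMI filter and UMI collapse
# --------------------------------------------------------------------------

def filter_chimeric_umis(records: pd.DataFrame,
                         min_share: float = 0.2) -> pd.DataFrame:
    """Drop (pair, side) combinations with a minority read share per UMI.

    Within each (cell, UMI), the read share of each BC1/BC2/capture-side
    combination is computed; combinations whose share falls below
    ``min_share`` are treated as PCR chimeras and removed.
    """
    if records.empty:
        return records.copy()
    grp = records.groupby(
        ["cell_bc", "umi", "bc1", "bc2", "capture_side"], sort=False
    )["read_count"].sum().reset_index()
    totals = grp.groupby(["cell_bc", "umi"], sort=False)["read_count"].transform("sum")
    share = grp["read_count"] / totals
    return grp[share >= min_share].reset_index(drop=True)


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _connected_component_count(umis: Sequence[str], max_dist: int = 1) -> int:
    """Components of the graph linking UMIs at Hamming distance ≤ max_dist."""
    n = len(umis)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if hamming(umis[i], umis[j]) <= max_dist:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    return len({find(i) for i in range(n)})


def collapse_umis(records: pd.DataFrame, max_hamming: int = 1) -> pd.DataFrame:
    """UMI counts per (cell, pair, side) as Hamming-graph components."""
    if records.empty:
        return pd.DataFrame(columns=["cell_bc", "bc1", "bc2", "capture_side",
                                     "umi_count"])
    rows = []
    for key, grp in records.groupby(["cell_bc", "bc1", "bc2", "capture_side"],
                                    sort=True):
        umis = sorted(grp["umi"].unique())
        rows.append((*key, _connected_component_count(umis, max_hamming)))
    return pd.DataFrame(rows, columns=["cell_bc", "bc1", "bc2",
                                       "capture_side", "umi_count"])


# --------------------------------------------------------------------------
# matrix
# --------------------------------------------------------------------------

@dataclass
class BcCellMatrix:
    """Sparse barcode-pair × cell UMI-count matrix (capture sides summed)."""

    matrix: sp.csr_matrix
    pairs: list[tuple[str, str]]
    cells: list[str]

    @property
    def pair_totals(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    @property
    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def subset(self, pair_mask: np.ndarray | None = None,
               cell_mask: np.ndarray | None = None) -> "BcCellMatrix":
        m = self.matrix
        pairs, cells = self.pairs, self.cells
        if pair_mask is not None:
            m = m[pair_mask]
            pairs = [p for p, k in zip(pairs, pair_mask) if k]
        if cell_mask is not None:
            m = m[:, cell_mask]
            cells = [c for c, k in zip(cells, cell_mask) if k]
        return BcCellMatrix(m.tocsr(), pairs, cells)

    def cell_pairs(self, min_umi: int = 1) -> dict[str, set[tuple[str, str]]]:
        """Detected pair set per cell at a UMI threshold."""
        out: dict[str, set[tuple[str, str]]] = {c: set() for c in self.cells}
        coo = self.matrix.tocoo()
        for r, c, v in zip(coo.row, coo.col, coo.data):
            if v >= min_umi:
                out[self.cells[c]].add(self.pairs[r])
        return out


def build_matrix(umi_counts: pd.DataFrame) -> BcCellMatrix:
    """Sum CS1/CS2 capture sides into one pair × cell count matrix."""
    if umi_counts.empty:
        return BcCellMatrix(sp.csr_matrix((0, 0), dtype=np.int64), [], [])
    summed = (umi_counts.groupby(["bc1", "bc2", "cell_bc"])["umi_count"]
              .sum().reset_index())
    pairs = sorted(set(zip(summed["bc1"], summed["bc2"])))
    cells = sorted(summed["cell_bc"].unique())
    pair_ix = {p: i for i, p in enumerate(pairs)}
    cell_ix = {c: i for i, c in enumerate(cells)}
    rows = [pair_ix[(b1, b2)] for b1, b2 in zip(summed["bc1"], summed["bc2"])]
    cols = [cell_ix[c] for c in summed["cell_bc"]]
    m = sp.coo_matrix((summed["umi_count"], (rows, cols)),
                      shape=(len(pairs), len(cells)), dtype=np.int64).tocsr()
    return BcCellMatrix(m, pairs, cells)


def qc_cells(qc_table: pd.DataFrame, min_umi: int = 1000,
             mito_range: tuple[float, float] = (1.0, 12.0),
             doublet_max: float = 0.4) -> set[str]:
    """Retain cells by transcriptome UMI, mito fraction and doublet score."""
    lo, hi = mito_range
    keep = ((qc_table["transcriptome_umi"] > min_umi)
            & (qc_table["mito_pct"] >= lo) & (qc_table["mito_pct"] <= hi)
            & (qc_table["doublet_score"] < doublet_max))
    return set(qc_table.loc[keep, "cell_bc"])


# --------------------------------------------------------------------------
# clonotype reconstruction
# --------------------------------------------------------------------------

@dataclass
class Clonotype:
    id: str
    barcode_pairs: frozenset
    provenance: str
    max_detection_fraction: float = float("nan")

    @property
    def n_pairs(self) -> int:
        return len(self.barcode_pairs)


def jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def _embed_and_cluster(matrix: BcCellMatrix, n_pcs: int, n_neighbors: int,
                       resolution: float, norm_scale: float,
                       seed: int) -> np.ndarray:
    """Community labels per cell from a PCA/kNN/Leiden pipeline."""
    import igraph
    import leidenalg
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    m = matrix.matrix.astype(float).T.toarray()  # cells x pairs
    totals = m.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    m = m / totals * norm_scale
    k = min(n_pcs, m.shape[0] - 1, m.shape[1] - 1)
    if k < 1:
        return np.zeros(m.shape[0], dtype=int)
    emb = PCA(n_components=k, random_state=seed).fit_transform(m)
    nn = min(n_neighbors, m.shape[0] - 1)
    if nn < 1:
        raise ValueError("fewer cells than the neighbor parameter requires")
    knn = NearestNeighbors(n_neighbors=nn).fit(emb)
    _, idx = knn.kneighbors(emb)
    edges = {(min(i, j), max(i, j))
             for i, row in enumerate(idx) for j in row if i != j}
    g = igraph.Graph(n=m.shape[0], edges=sorted(edges))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed)
    return np.array(part.membership)


def _rank_inflection_cut(fractions: np.ndarray, ratio_cut: float) -> int:
    """Number of leading ranks kept before the first ratio > ratio_cut.

    Fractions are ranked over the full pair universe, so a clean community
    inflects where its clone's pairs give way to undetected pairs. A drop
    to zero — including the implicit one past the end of the ranked list —
    is an infinite fold change and counts as the inflection. Returns 0 only
    when no fold change exceeds the cut before the fractions flatten out
    (no inflection → candidate rejected).
    """
    order = np.sort(fractions)[::-1]
    if len(order) == 0 or order[0] == 0:
        return 0
    for n in range(len(order) - 1):
        nxt = order[n + 1]
        if nxt == 0 or order[n] / nxt > ratio_cut:
            return n + 1
    return len(order)


def _is_doublet_clonotype(sub: np.ndarray, cross_frac: float = 0.1) -> bool:
    """Spectral bipartition test of the pair co-detection matrix.

    ``sub`` is the binary pairs × member-cells detection matrix of one
    candidate clonotype. If its pair–pair co-detection matrix splits into
    two blocks whose cross-block co-detection is under ``cross_frac`` of
    the within-block level, the candidate is two clones fused by a doublet.
    """
    if sub.shape[0] < 4 or sub.shape[1] < 4:
        return False
    co = (sub @ sub.T).astype(float)
    deg = co.sum(axis=1)
    if np.any(deg == 0):
        return False
    d = 1.0 / np.sqrt(deg)
    lap = np.eye(co.shape[0]) - (co * d).T * d
    vals, vecs = np.linalg.eigh(lap)
    fiedler = vecs[:, 1]
    a = fiedler >= np.median(fiedler)
    if a.all() or (~a).all():
        return False
    within_a = co[np.ix_(a, a)]
    within_b = co[np.ix_(~a, ~a)]
    cross = co[np.ix_(a, ~a)]
    wa = within_a[~np.eye(within_a.shape[0], dtype=bool)].mean() if within_a.shape[0] > 1 else 0.0
    wb = within_b[~np.eye(within_b.shape[0], dtype=bool)].mean() if within_b.shape[0] > 1 else 0.0
    within = (wa + wb) / 2
    if within <= 0:
        return False
    return cross.mean() < cross_frac * within


def _merge_by_jaccard(candidates: list[frozenset], connect: float
                      ) -> list[frozenset]:
    """Connect candidates with Jaccard > connect; intersect each component."""
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(range(len(candidates)))
    for i, j in itertools.combinations(range(len(candidates)), 2):
        if jaccard(candidates[i], candidates[j]) > connect:
            g.add_edge(i, j)
    merged = []
    for comp in nx.connected_components(g):
        sets = [candidates[i] for i in sorted(comp)]
        inter = frozenset.intersection(*sets)
        if inter:
            merged.append(inter)
    return merged


def reconstruct_clonotypes(matrix: BcCellMatrix, config,
                           exclude_cells: set[str] = frozenset(),
                           provenance: str = "de_novo_round1",
                           seed: int | None = None) -> list[Clonotype]:
    """De novo clonotype discovery from the pair × cell matrix.

    Steps: (i) zero entries below ``clonotype_min_umi_per_pair``; (ii) drop
    cells and pairs below the total-UMI floors; (iii) embed cells
    (library-size normalization → top PCs → kNN graph → Leiden communities
    at resolution 1); (iv) per community, rank pair detection fractions and
    cut at the first fold-change above ``rank_ratio_cut``; (v) keep
    candidates with max detection fraction > 0.5 and > 6 pairs; (vi) drop
    candidates whose co-detection matrix is a two-block doublet; (vii)
    merge near-duplicate candidates on a Jaccard graph.
    """
    seed = config.seed if seed is None else seed
    if exclude_cells:
        mask = np.array([c not in exclude_cells for c in matrix.cells])
        matrix = matrix.subset(cell_mask=mask)
    m = matrix.matrix.copy()
    m.data = np.where(m.data >= config.clonotype_min_umi_per_pair, m.data, 0)
    m.eliminate_zeros()
    work = BcCellMatrix(m.tocsr(), matrix.pairs, matrix.cells)
    cell_keep = work.cell_totals >= config.min_cell_total_umi
    pair_keep = work.pair_totals >= config.min_pair_total_umi
    work = work.subset(pair_mask=pair_keep, cell_mask=cell_keep)
    if len(work.cells) == 0 or len(work.pairs) == 0:
        return []
    labels = _embed_and_cluster(work, config.n_pcs, config.knn_neighbors,
                                config.leiden_resolution,
                                config.sc_norm_scale, seed)
    binary = (work.matrix > 0).astype(np.int8).toarray()
    candidates: list[tuple[frozenset, float]] = []
    for lab in np.unique(labels):
        member = labels == lab
        if member.sum() == 0:
            continue
        frac = binary[:, member].mean(axis=1)
        n_keep = _rank_inflection_cut(frac, config.rank_ratio_cut)
        if n_keep == 0:
            continue
        order = np.argsort(-frac, kind="stable")[:n_keep]
        max_frac = float(frac[order[0]])
        if max_frac <= config.min_max_detection_fraction:
            continue
        if n_keep < config.min_clonotype_pairs:
            continue
        if _is_doublet_clonotype(binary[np.ix_(order, member)]):
            continue
        candidates.append(
            (frozenset(work.pairs[i] for i in order), max_frac))
    merged = _merge_by_jaccard([c for c, _ in candidates],
                               config.jaccard_connect)
    frac_of = {c: f for c, f in candidates}
    out = []
    for i, pairs in enumerate(sorted(merged, key=lambda s: sorted(s))):
        best = max((frac_of[c] for c, _ in candidates
                    if pairs <= c), default=float("nan"))
        out.append(Clonotype(f"{provenance}.c{i:03d}", pairs, provenance, best))
    return out


def merge_with_bulk(de_novo: list[Clonotype],
                    bulk_sets: Mapping[str, Iterable[tuple[str, str]]],
                    jaccard_bulk: float = 0.05) -> list[Clonotype]:
    """Union de novo clonotypes with non-overlapping bulk clonotypes.

    A bulk set with Jaccard > ``jaccard_bulk`` against any de novo
    clonotype is treated as the same clone (the de novo version is kept).
    """
    out = list(de_novo)
    for name, pairs in sorted(bulk_sets.items()):
        fs = frozenset(tuple(p) for p in pairs)
        if any(jaccard(fs, c.barcode_pairs) > jaccard_bulk for c in de_novo):
            continue
        out.append(Clonotype(f"bulk.{name}", fs, "bulk"))
    return out


# --------------------------------------------------------------------------
# cell assignment
# --------------------------------------------------------------------------

ASSIGNMENT_COLUMNS = ["cell_bc", "clonotype_id", "top_precision",
                      "top_recall", "second_recall", "status"]


def assign_cells(matrix: BcCellMatrix, clonotypes: Sequence[Clonotype],
                 min_umi: int = 2, min_recall: float = 0.1,
                 min_precision: float = 0.75,
                 second_recall_max: float = 0.1) -> pd.DataFrame:
    """Assign each cell to its best clonotype by barcode-1 precision.

    Assignment uses the set of barcode-1 values detected at ≥ ``min_umi``
    in the cell (single barcodes rather than pairs, so rearranged cells are
    not penalized). Precision = fraction of the cell's barcodes from the
    clonotype; recall = fraction of the clonotype's barcodes seen. A cell
    is assigned iff top_recall > 0.1 and top_precision > 0.75, rejected as
    a probable doublet when the second-best recall exceeds 0.1, and labeled
    low_capture when the best recall is below threshold.
    """
    clono_bc1 = [frozenset(b1 for b1, _ in c.barcode_pairs) for c in clonotypes]
    per_cell = matrix.cell_pairs(min_umi=min_umi)
    rows = []
    for cell in matrix.cells:
        detected = frozenset(b1 for b1, _ in per_cell[cell])
        if not detected or not clonotypes:
            rows.append((cell, "unassigned", 0.0, 0.0, 0.0, "low_capture"))
            continue
        stats = []
        for c, bcs in zip(clonotypes, clono_bc1):
            inter = len(detected & bcs)
            precision = inter / len(detected)
            recall = inter / len(bcs) if bcs else 0.0
            stats.append((precision, recall, c.id))
        stats.sort(key=lambda t: (-t[0], -t[1], t[2]))
        top_p, top_r, top_id = stats[0]
        second_r = max((r for _, r, cid in stats if cid != top_id),
                       default=0.0)
        if top_r > min_recall and top_p > min_precision:
            if second_r > second_recall_max:
                rows.append((cell, "unassigned", top_p, top_r, second_r,
                             "ambiguous/doublet"))
            else:
                rows.append((cell, top_id, top_p, top_r, second_r, "assigned"))
        elif top_r <= min_recall:
            rows.append((cell, "unassigned", top_p, top_r, second_r,
                         "low_capture"))
        else:
            rows.append((cell, "unassigned", top_p, top_r, second_r,
                         "low_capture"))
    return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)


def iterate_rounds(matrix: BcCellMatrix, config,
                   bulk_sets: Mapping[str, Iterable[tuple[str, str]]] | None = None,
                   max_rounds: int = 5) -> tuple[list[Clonotype], pd.DataFrame]:
    """Iterative clonotype discovery: assign, remove, re-reconstruct.

    Round 1 clonotypes (merged with bulk sets if given) assign cells; the
    assignable cells are removed and reconstruction repeats on the
    remainder until a round adds no clonotype. Returns the final clonotype
    list and the final assignment of all cells.
    """
    clonotypes = reconstruct_clonotypes(matrix, config,
                                        provenance="de_novo_round1",
                                        seed=config.seed)
    if bulk_sets:
        clonotypes = merge_with_bulk(clonotypes, bulk_sets,
                                     config.jaccard_bulk)
    for round_i in range(2, max_rounds + 1):
        assignments = assign_cells(matrix, clonotypes, config.assign_min_umi,
                                   config.assign_min_recall,
                                   config.assign_min_precision,
                                   config.doublet_second_recall)
        taken = set(assignments.loc[assignments["status"] == "assigned",
                                    "cell_bc"])
        residual = reconstruct_clonotypes(
            matrix, config, exclude_cells=taken,
            provenance=f"de_novo_round{round_i}", seed=config.seed + round_i)
        new = [c for c in residual
               if all(jaccard(c.barcode_pairs, k.barcode_pairs)
                      <= config.jaccard_connect for k in clonotypes)]
        if not new:
            break
        clonotypes = clonotypes + new
    assignments = assign_cells(matrix, clonotypes, config.assign_min_umi,
                               config.assign_min_recall,
                               config.assign_min_precision,
                               config.doublet_second_recall)
    return clonotypes, assignments


# --------------------------------------------------------------------------
# precision-recall threshold analysis
# --------------------------------------------------------------------------

def pr_threshold_analysis(matrix: BcCellMatrix, assignments: pd.DataFrame,
                          clonotypes: Sequence[Clonotype],
                          thresholds: Iterable[int] = range(1, 11)
                          ) -> pd.DataFrame:
    """Mean detection precision/recall vs the assigned clonotype, per UMI
    threshold, averaged over confidently assigned cells."""
    clono_by_id = {c.id: c.barcode_pairs for c in clonotypes}
    assigned = assignments[assignments["status"] == "assigned"]
    rows = []
    for t in thresholds:
        per_cell = matrix.cell_pairs(min_umi=t)
        precisions, recalls = [], []
        for rec in assigned.itertuples(index=False):
            expected = clono_by_id[rec.clonotype_id]
            detected = per_cell.get(rec.cell_bc, set())
            if detected:  # precision undefined for empty detection
                precisions.append(len(detected & expected) / len(detected))
            recalls.append(len(detected & expected) / len(expected)
                           if expected else 0.0)
        rows.append((t,
                     float(np.mean(precisions)) if precisions else float("nan"),
                     float(np.mean(recalls)) if recalls else float("nan")))
    return pd.DataFrame(rows, columns=["umi_threshold", "mean_precision",
                                       "mean_recall"])


# --------------------------------------------------------------------------
# single-cell rearrangement calling
# --------------------------------------------------------------------------

SC_CALL_EXTRA = ["cell_bc", "clonotype_id", "congruent"]


def call_sc_rearrangements(matrix: BcCellMatrix, bonafide: pd.DataFrame,
                           clonotypes: Sequence[Clonotype],
                           assignments: pd.DataFrame,
                           min_umi: int = 2) -> pd.DataFrame:
    """Call rearrangements per assigned cell; keep congruent calls.

    A novel pair detected at ≥ ``min_umi`` UMIs in an assigned cell is
    congruent iff both member barcodes belong to the cell's assigned
    clonotype; incongruent calls are flagged (probable ambient RNA) and
    retained with ``congruent=False`` for reporting.
    """
    clono_by_id = {c.id: c.barcode_pairs for c in clonotypes}
    assigned = assignments[assignments["status"] == "assigned"]
    per_cell = matrix.cell_pairs(min_umi=min_umi)
    coo = matrix.matrix.tocoo()
    umi_of: dict[tuple[str, tuple[str, str]], int] = {}
    for r, c, v in zip(coo.row, coo.col, coo.data):
        umi_of[(matrix.cells[c], matrix.pairs[r])] = int(v)
    out_rows = []
    for rec in assigned.itertuples(index=False):
        clono_pairs = clono_by_id[rec.clonotype_id]
        clono_bc1 = {b1 for b1, _ in clono_pairs}
        clono_bc2 = {b2 for _, b2 in clono_pairs}
        detected = per_cell.get(rec.cell_bc, set())
        counts = pd.DataFrame(
            [(b1, b2, umi_of[(rec.cell_bc, (b1, b2))],
              umi_of[(rec.cell_bc, (b1, b2))]) for b1, b2 in sorted(detected)],
            columns=["bc1", "bc2", "read_count", "umi_count"])
        result: CallResult = call_rearrangements(counts, bonafide,
                                                 min_umi=min_umi)
        for call in result.calls.itertuples(index=False):
            congruent = (call.bc1 in clono_bc1 and call.bc2 in clono_bc2)
            out_rows.append((*call, rec.cell_bc, rec.clonotype_id, congruent))
    from .bulk_svcalls import REARRANGEMENT_COLUMNS
    return pd.DataFrame(out_rows,
                        columns=REARRANGEMENT_COLUMNS + SC_CALL_EXTRA)


# --------------------------------------------------------------------------
# raw-FASTQ route (10x 3' layout)
# --------------------------------------------------------------------------

def write_sc_fastq(records: pd.DataFrame, prefix, design=DEFAULT_DESIGN,
                   read2_len: int = 96) -> tuple:
    """Serialize simulator T7 records as a 10x-layout FASTQ pair.

    Read 1 = 16-nt cell barcode + 12-nt UMI; read 2 = the captured
    transcript with the anchors at their expected offsets. One read per
    record per read_count.
    """
    from .io import write_fastq
    from .simulate import sc_read2_sequence
    from pathlib import Path

    prefix = Path(prefix)
    r1s, r2s = [], []
    for i, rec in enumerate(records.itertuples(index=False)):
        seq2 = sc_read2_sequence(design, rec.bc1, rec.bc2,
                                 rec.capture_side, read2_len)
        for k in range(int(rec.read_count)):
            name = f"t7r{i:08d}.{k}"
            r1s.append((name, rec.cell_bc + rec.umi))
            r2s.append((name, seq2))
    p1 = prefix.parent / (prefix.name + "_R1.fastq.gz")
    p2 = prefix.parent / (prefix.name + "_R2.fastq.gz")
    write_fastq(r1s, p1)
    write_fastq(r2s, p2)
    return p1, p2


def records_from_fastq(r1_path, r2_path, whitelist: set[str] | None = None,
                       design=DEFAULT_DESIGN) -> pd.DataFrame:
    """Parse a 10x-layout FASTQ pair back into T7 records."""
    from .io import read_fastq

    rows = []
    for (n1, s1, _), (n2, s2, _) in zip(read_fastq(r1_path),
                                        read_fastq(r2_path)):
        rec = extract_t7_record(s1, s2, whitelist, design)
        if rec is not None:
            rows.append(rec)
    df = pd.DataFrame(rows, columns=T7_RECORD_COLUMNS)
    if df.empty:
        return df
    return (df.groupby(["cell_bc", "umi", "bc1", "bc2", "capture_side"],
                       sort=True)["read_count"].sum().reset_index())


# --------------------------------------------------------------------------
# convenience: records -> matrix
# --------------------------------------------------------------------------

def matrix_from_records(records: pd.DataFrame, config,
                        retained_cells: set[str] | None = None
                        ) -> BcCellMatrix:
    """Chimera-filter, UMI-collapse and matrix-build in one call."""
    rec = records
    if retained_cells is not None:
        rec = rec[rec["cell_bc"].isin(retained_cells)]
    rec = filter_chimeric_umis(rec, config.chimera_min_share)
    counts = collapse_umis(rec, config.umi_hamming)
    return build_matrix(counts)
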