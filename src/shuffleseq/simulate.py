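"""Mechanistic simulator of a shuffle-cassette genome-rearrangement experiment.

The simulated experiment: a diploid two-haplotype genome receives ~50
piggyBac integrations of a 176-bp "shuffle cassette" per founder clone at
TTAA tetranucleotides (with target-site duplication). Each cassette carries
two random 20-nt barcodes flanking a palindromic loxPsym site, two 10x
capture sequences (CS2 left of the loxPsym site, CS1 right of it on the top
strand), and convergent T7 promoters. Cre recombination between two
cassettes of the same clone exchanges the barcode halves, so every
structural variant (deletion, inversion, translocation, ecDNA) is readable
as a novel barcode pair. The module emits the three read types the analysis
stages consume — T7 IVT mapping reads, bulk amplicon reads with UMIs, and
single-cell T7 feature reads — together with complete truth tables.

Coordinates: ``pos`` of an insertion is the 1-based first base of the TTAA
that is duplicated on the left side of the cassette. Internal arithmetic is
0-based half-open; TSV output is 1-based, BED output 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# sequence utilities
# --------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, err_rate: float) -> str:
    """Uniform substitution errors; no indels."""
    if err_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < err_rate)[0]
    if hits.size == 0:
        return seq
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


# --------------------------------------------------------------------------
# cassette design
# --------------------------------------------------------------------------

#: 34-bp palindromic loxPsym site: symmetric spacer, so recombination
#: between two sites resolves in either register with equal probability.
LOXPSYM = "ATAACTTCGTATAATGTACATTATACGAAGTTAT"

#: 10x Genomics feature-barcoding capture sequences.
CAPTURE_SEQ_1 = "GCTTTAAGGCCGGTCCTAGCAA"
CAPTURE_SEQ_2 = "GCTCACCTATTAGCGGCTAAGG"

T7_PROMOTER = "TAATACGACTCACTATAGGG"


@dataclass(frozen=True)
class CassetteDesign:
    """Element layout of the shuffle cassette (top strand, left to right).

    The assembled template is
    ``t7_fwd + cs2 + primer_left + BC1 + loxPsym + BC2 + cs1 + primer_right
    + t7_rev`` and must total ``total_length`` bp. ``primer_left`` must end
    in the TGAGC anchor used for barcode extraction; ``cs1`` must begin with
    GCTTT so that its reverse complement provides the AAAGC anchor.
    """

    t7_promoter_fwd: str = T7_PROMOTER
    capture_seq_2: str = CAPTURE_SEQ_2
    primer_site_left: str = "GTCGATGAGC"
    bc1_length: int = 20
    loxpsym: str = LOXPSYM
    bc2_length: int = 20
    capture_seq_1: str = CAPTURE_SEQ_1
    primer_site_right: str = "ATCGGTAC"
    t7_promoter_rev: str = revcomp(T7_PROMOTER)
    total_length: int = 176

    def __post_init__(self) -> None:
        if not self.primer_site_left.endswith("TGAGC"):
            raise ValueError("primer_site_left must end in the TGAGC anchor")
        if not self.capture_seq_1.startswith("GCTTT"):
            raise ValueError("capture_seq_1 must start with GCTTT (AAAGC anchor)")
        if not (self.loxpsym.startswith("ATAAC") and self.loxpsym.endswith("GTTAT")):
            raise ValueError("loxpsym must begin ATAAC and end GTTAT")
        fixed = (len(self.t7_promoter_fwd) + len(self.capture_seq_2)
                 + len(self.primer_site_left) + self.bc1_length + len(self.loxpsym)
                 + self.bc2_length + len(self.capture_seq_1)
                 + len(self.primer_site_right) + len(self.t7_promoter_rev))
        if fixed != self.total_length:
            raise ValueError(
                f"assembled cassette length {fixed} != configured {self.total_length}")

    @property
    def bc1_offset(self) -> int:
        """0-based offset of BC1 in the assembled top strand."""
        return (len(self.t7_promoter_fwd) + len(self.capture_seq_2)
                + len(self.primer_site_left))

    @property
    def bc2_offset(self) -> int:
        return self.bc1_offset + self.bc1_length + len(self.loxpsym)


DEFAULT_DESIGN = CassetteDesign()

_BC_RE = re.compile(r"^[ACGT]+$")


def build_cassette(design: CassetteDesign, bc1: str, bc2: str) -> str:
    """Assemble the top-strand cassette template for one barcode pair."""
    if len(bc1) != design.bc1_length or len(bc2) != design.bc2_length:
        raise ValueError(
            f"barcode lengths ({len(bc1)}, {len(bc2)}) do not match design "
            f"({design.bc1_length}, {design.bc2_length})")
    if not (_BC_RE.match(bc1) and _BC_RE.match(bc2)):
        raise ValueError("barcodes must be over the alphabet ACGT")
    return (design.t7_promoter_fwd + design.capture_seq_2 + design.primer_site_left
            + bc1 + design.loxpsym + bc2 + design.capture_seq_1
            + design.primer_site_right + design.t7_promoter_rev)


# --------------------------------------------------------------------------
# genome model
# --------------------------------------------------------------------------

@dataclass
class GenomeModel:
    """A small diploid genome with dense heterozygous SNVs.

    Both haplotypes share coordinates (variants are substitutions only and
    never fall inside a TTAA motif), so ``ttaa_sites`` are valid on both.
    """

    chromosomes: list[tuple[str, int]]
    haplotypes: tuple[str, str]
    variants: pd.DataFrame              # chrom, pos (1-based), ref, alt
    ttaa_sites: dict[str, np.ndarray]   # 1-based motif start positions
    sequence: dict[str, dict[str, str]]  # haplotype -> chrom -> sequence

    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]


def simulate_reference(
    chrom_lengths: dict[str, int],
    variant_spacing: float = 150.0,
    haplotypes: tuple[str, str] = ("BL6", "CAST"),
    seed: int = 0,
) -> GenomeModel:
    """Generate a random two-haplotype reference genome.

    ``variant_spacing`` is the mean distance between heterozygous SNVs
    (0 disables variants). TTAA motifs are located on the first haplotype
    and, because variants avoid them, are shared by the second.
    """
    rng = np.random.default_rng(seed)
    ref: dict[str, str] = {}
    alt: dict[str, str] = {}
    ttaa: dict[str, np.ndarray] = {}
    var_rows: list[tuple[str, int, str, str]] = []
    for chrom, length in chrom_lengths.items():
        seq = random_dna(rng, length)
        sites = np.array([m.start() + 1 for m in re.finditer("TTAA", seq)],
                         dtype=np.int64)
        if sites.size == 0:
            raise ValueError(f"no TTAA sites on simulated chromosome {chrom}")
        ttaa[chrom] = sites
        covered = np.zeros(length, dtype=bool)
        for s in sites:  # 1-based motif start
            covered[s - 1:s + 3] = True
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        if variant_spacing and variant_spacing > 0:
            n_var = rng.poisson(length / variant_spacing)
            cand = rng.choice(length, size=min(n_var, length), replace=False)
            cand = np.sort(cand[~covered[cand]])
            for p0 in cand:
                ref_base = chr(arr[p0])
                alt_base = chr(rng.choice(_BASES[_BASES != arr[p0]]))
                var_rows.append((chrom, int(p0) + 1, ref_base, alt_base))
                arr[p0] = ord(alt_base)
        ref[chrom] = seq
        alt[chrom] = arr.tobytes().decode("ascii")
    variants = pd.DataFrame(var_rows, columns=["chrom", "pos", "ref", "alt"])
    return GenomeModel(
        chromosomes=list(chrom_lengths.items()),
        haplotypes=haplotypes,
        variants=variants,
        ttaa_sites=ttaa,
        sequence={haplotypes[0]: ref, haplotypes[1]: alt},
    )


# --------------------------------------------------------------------------
# insertions
# --------------------------------------------------------------------------

INSERTION_COLUMNS = ["insertion_id", "clone_id", "chrom", "pos",
                     "orientation", "allele", "bc1", "bc2"]

TOP = "top-CS2"      # CS2 toward the lower genomic coordinate
BOTTOM = "bottom-CS1"  # cassette integrated in reverse complement


def place_insertions(
    genome: GenomeModel,
    n_clones: int,
    insertions_per_clone: int,
    seed: int = 0,
    design: CassetteDesign = DEFAULT_DESIGN,
) -> pd.DataFrame:
    """Drop cassettes at TTAA sites, without replacement across the
    population.

    On a genome-scale reference, independent integrations in different
    clones essentially never hit the same TTAA; sampling sites without
    replacement across all clones reproduces that sparsity on the small
    simulated genome. Barcode pairs are globally unique; orientation and
    haplotype are uniform.
    """
    rng = np.random.default_rng(seed)
    pool = [(chrom, int(p)) for chrom, sites in genome.ttaa_sites.items()
            for p in sites]
    if n_clones * insertions_per_clone > len(pool):
        raise ValueError(
            f"requested {n_clones * insertions_per_clone} insertions but "
            f"only {len(pool)} TTAA sites are available")
    seen_bc: set[str] = set()

    def fresh_barcode(length: int) -> str:
        while True:
            bc = random_dna(rng, length)
            if bc not in seen_bc:
                seen_bc.add(bc)
                return bc

    rows = []
    idx = 0
    chosen_all = rng.choice(len(pool), size=n_clones * insertions_per_clone,
                            replace=False)
    for clone in range(n_clones):
        chosen = chosen_all[clone * insertions_per_clone:
                            (clone + 1) * insertions_per_clone]
        for j in np.sort(chosen):
            chrom, pos = pool[j]
            rows.append((
                f"ins{idx:06d}", f"clone{clone:04d}", chrom, pos,
                TOP if rng.random() < 0.5 else BOTTOM,
                genome.haplotypes[int(rng.random() < 0.5)],
                fresh_barcode(design.bc1_length),
                fresh_barcode(design.bc2_length),
            ))
            idx += 1
    return pd.DataFrame(rows, columns=INSERTION_COLUMNS)


# --------------------------------------------------------------------------
# Cre recombination
# --------------------------------------------------------------------------

EVENT_COLUMNS = ["event_id", "clone_id", "ins_a", "ins_b", "register",
                 "resolved_class"]
DERIV_COLUMNS = ["deriv_id", "event_id", "clone_id", "left_bc", "left_cs",
                 "right_bc", "right_cs", "topology", "detectable",
                 "bc1", "bc2", "sv_class", "size", "scar_or_ecdna",
                 "left_src_ins", "left_src_side", "right_src_ins",
                 "right_src_side"]

DIRECT = "direct"
INVERTED = "inverted"


def _halves(ins: pd.Series) -> tuple[dict, dict]:
    """Genome-frame left/right cassette halves around the loxPsym site."""
    if ins["orientation"] == TOP:
        left = {"bc": ins["bc1"], "cs": "CS2", "ins": ins["insertion_id"],
                "flank": "left"}
        right = {"bc": ins["bc2"], "cs": "CS1", "ins": ins["insertion_id"],
                 "flank": "right"}
    else:
        left = {"bc": ins["bc2"], "cs": "CS1", "ins": ins["insertion_id"],
                "flank": "left"}
        right = {"bc": ins["bc1"], "cs": "CS2", "ins": ins["insertion_id"],
                 "flank": "right"}
    return left, right


def cross_products(ins_a: pd.Series, ins_b: pd.Series, register: str,
                   cis: bool) -> list[dict]:
    """Join the two cassettes at their loxPsym sites.

    Direct register preserves reading direction (deletion + circle in cis);
    inverted register flips the intervening segment (inversion in cis). For
    trans events both registers yield two reciprocal genomic products.
    Returns two products as dicts with left/right half descriptors.
    """
    a_left, a_right = _halves(ins_a)
    b_left, b_right = _halves(ins_b)
    if register == DIRECT:
        p1 = {"left": a_left, "right": b_right, "topology": "genomic"}
        # in cis the excised segment between the two sites circularises
        p2 = {"left": b_left, "right": a_right,
              "topology": "circle" if cis else "genomic"}
    else:
        # the intervening segment is reverse-complemented in place
        p1 = {"left": a_left, "right": dict(b_left), "topology": "genomic"}
        p2 = {"left": dict(a_right), "right": b_right, "topology": "genomic"}
        # flipping a genome-left half puts its parental flank on the
        # product's right, and vice versa; flank labels stay parental
    return [p1, p2]


def apply_cre_events(
    insertions: pd.DataFrame,
    rate: float = 5.0,
    cis_decay_lambda: float = 200_000.0,
    trans_rate: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw recombination events within clones and compute their products.

    The number of events per clone is Poisson(``rate``). A cis partner pair
    (same chromosome) is chosen with probability proportional to
    ``exp(-distance / cis_decay_lambda)``; with probability ``trans_rate``
    the event instead joins cassettes on different chromosomes (uniformly).
    The loxPsym register is an independent fair coin.

    Returns ``(events, derivatives)`` tables.
    """
    if cis_decay_lambda <= 0:
        raise ValueError("cis_decay_lambda must be > 0")
    rng = np.random.default_rng(seed)
    ev_rows: list[tuple] = []
    dv_rows: list[tuple] = []
    by_id = insertions.set_index("insertion_id")
    ev_idx = 0
    for clone_id, sub in insertions.groupby("clone_id", sort=True):
        sub = sub.sort_values(["chrom", "pos"]).reset_index(drop=True)
        n = len(sub)
        if n < 2:
            continue
        ii, jj = np.triu_indices(n, k=1)
        same = (sub["chrom"].values[ii] == sub["chrom"].values[jj])
        dist = np.abs(sub["pos"].values[ii] - sub["pos"].values[jj])
        cis_idx = np.nonzero(same)[0]
        trans_idx = np.nonzero(~same)[0]
        cis_w = np.exp(-dist[cis_idx] / cis_decay_lambda)
        cis_cum = np.cumsum(cis_w)
        cis_total = cis_cum[-1] if cis_cum.size else 0.0
        k = rng.poisson(rate)
        for _ in range(k):
            go_trans = rng.random() < trans_rate
            if go_trans and trans_idx.size == 0:
                go_trans = False
            if not go_trans and (cis_idx.size == 0 or cis_total == 0):
                if trans_idx.size == 0:
                    continue
                go_trans = True
            if go_trans:
                pick = trans_idx[rng.integers(trans_idx.size)]
            else:
                j = int(np.searchsorted(cis_cum, rng.random() * cis_total,
                                        side="right"))
                pick = cis_idx[min(j, cis_idx.size - 1)]
            a = sub.iloc[int(ii[pick])]
            b = sub.iloc[int(jj[pick])]
            cis = a["chrom"] == b["chrom"]
            register = DIRECT if rng.random() < 0.5 else INVERTED
            if cis:
                resolved = "deletion" if register == DIRECT else "inversion"
            else:
                resolved = "translocation_reciprocal"
            event_id = f"ev{ev_idx:06d}"
            ev_rows.append((event_id, clone_id, a["insertion_id"],
                            b["insertion_id"], register, resolved))
            size = int(abs(a["pos"] - b["pos"])) if cis else -1
            for prod_i, prod in enumerate(cross_products(a, b, register, cis)):
                L, R = prod["left"], prod["right"]
                detectable = L["cs"] != R["cs"]
                if detectable:
                    bc1 = L["bc"] if L["cs"] == "CS2" else R["bc"]
                    bc2 = R["bc"] if R["cs"] == "CS1" else L["bc"]
                else:
                    bc1 = bc2 = ""
                if resolved == "translocation_reciprocal":
                    sv_class = "translocation"
                elif resolved == "deletion":
                    sv_class = "deletion"
                else:
                    sv_class = "inversion"
                scar_or_ecdna = ""
                if sv_class == "deletion":
                    scar_or_ecdna = ("ecDNA" if prod["topology"] == "circle"
                                     else "genomic_scar")
                dv_rows.append((
                    f"{event_id}.p{prod_i}", event_id, clone_id,
                    L["bc"], L["cs"], R["bc"], R["cs"], prod["topology"],
                    detectable, bc1, bc2, sv_class, size, scar_or_ecdna,
                    L["ins"], L["flank"], R["ins"], R["flank"],
                ))
            ev_idx += 1
    events = pd.DataFrame(ev_rows, columns=EVENT_COLUMNS)
    derivs = pd.DataFrame(dv_rows, columns=DERIV_COLUMNS)
    _ = by_id  # kept for clarity of intent
    return events, derivs


# --------------------------------------------------------------------------
# experiment state
# --------------------------------------------------------------------------

@dataclass
class SimState:
    """Complete truth for one simulated experiment."""

    design: CassetteDesign
    genome: GenomeModel
    insertions: pd.DataFrame
    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EVENT_COLUMNS))
    derivatives: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=DERIV_COLUMNS))
    seed: int = 0

    def detectable_derivatives(self) -> pd.DataFrame:
        if self.derivatives.empty:
            return self.derivatives
        return self.derivatives[self.derivatives["detectable"]].reset_index(drop=True)

    def parental_pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.insertions["bc1"], self.insertions["bc2"]))


def simulate_experiment(config, with_events: bool = True) -> SimState:
    """Build genome, clones, insertions and (optionally) Cre events."""
    genome = simulate_reference(config.chrom_lengths, config.variant_spacing,
                                config.haplotypes, seed=config.seed)
    insertions = place_insertions(genome, config.n_clones,
                                  config.insertions_per_clone,
                                  seed=config.seed + 1)
    state = SimState(DEFAULT_DESIGN, genome, insertions, seed=config.seed)
    if with_events:
        state.events, state.derivatives = apply_cre_events(
            insertions, rate=config.cre_rate,
            cis_decay_lambda=config.cis_decay_lambda,
            trans_rate=config.trans_rate, seed=config.seed + 2)
    return state


# --------------------------------------------------------------------------
# IVT read emission (insertion-site mapping / SV validation reads)
# --------------------------------------------------------------------------

IVT_READ_COLUMNS = ["read_id", "read1", "read2", "read1_umi", "source_id",
                    "side", "frame", "chrom", "junction_pos", "haplotype"]

#: bases of cassette context kept before the extraction anchor in read 1 /
#: single-cell read 2, so the anchor match starts at position 15 (1-based).
_ANCHOR_PREFIX = 14


def _frame_read(design: CassetteDesign, bc1: str, bc2: str, frame: str,
                read_len: int) -> str:
    """Barcode-carrying read for one transcript frame.

    ``frame`` is ``top-CS2`` (TGAGC·BC1·ATAAC … GTTAT·BC2) or ``bottom-CS1``
    (AAAGC·rc(BC2)·ATAAC … GTTAT·rc(BC1)), each preceded by 14 nt of
    cassette context.
    """
    cassette = build_cassette(design, bc1, bc2)
    if frame == TOP:
        start = design.bc1_offset - 5 - _ANCHOR_PREFIX
        seq = cassette[start:]
    else:
        rc = revcomp(cassette)
        # AAAGC = rc(GCTTT) begins at rc-offset of the CS1 5' end
        cs1_start = design.bc2_offset + design.bc2_length
        start = (design.total_length - (cs1_start + 5)) - _ANCHOR_PREFIX
        seq = rc[start:]
    return seq[:read_len]


def _flank_read2(genome: GenomeModel, hap: str, chrom: str, pos: int,
                 side: str, flank_len: int) -> str | None:
    """Genomic read 2 for one cassette side.

    Left-side reads are the top strand ending at the left-TTAA 3' end
    (plus-strand alignment); right-side reads are the reverse complement of
    the duplicated-TTAA-onward slice (minus-strand alignment). Both start at
    the RT-priming (far) end, whose first 8 nt double as the read-2 UMI.
    """
    seq = genome.sequence[hap][chrom]
    if side == "left":
        lo = pos + 3 - flank_len
        if lo < 0:
            return None
        return seq[lo:pos + 3]
    hi = pos - 1 + flank_len
    if hi > len(seq):
        return None
    return revcomp(seq[pos - 1:hi])


def emit_ivt_reads(
    state: SimState,
    depth_per_side: int = 10,
    read_len: int = 120,
    err_rate: float = 0.001,
    seed: int = 0,
    flank_min: int = 30,
    flank_max: int = 110,
    include_derivatives: bool = False,
    include_insertions: bool = True,
) -> pd.DataFrame:
    """Emit T7 IVT read pairs for every cassette end.

    Each parental insertion (and, optionally, each detectable derivative
    cassette) emits ``depth_per_side`` read pairs per side. Read 1 carries
    the barcode region in the side's transcript frame; read 2 carries
    flanking genomic sequence of per-read random length, ending at the
    junction. Substitution errors are applied at ``err_rate``.
    """
    design = state.design
    if read_len < _ANCHOR_PREFIX + 5 + design.bc1_length + len(design.loxpsym) + design.bc2_length:
        raise ValueError("read_len shorter than the barcode region")
    if flank_max <= flank_min:
        raise ValueError("flank_max must exceed flank_min")
    rng = np.random.default_rng(seed)
    by_id = state.insertions.set_index("insertion_id")
    rows: list[tuple] = []
    rid = 0

    def emit(source_id: str, bc1: str, bc2: str, left_like_top: bool,
             left_src: tuple[str, str], right_src: tuple[str, str]) -> None:
        nonlocal rid
        # side -> (transcript frame, parental flank source)
        # a top-CS2-like cassette reads CS2-frame into its right flank
        sides = {
            "left": (BOTTOM if left_like_top else TOP, left_src),
            "right": (TOP if left_like_top else BOTTOM, right_src),
        }
        for side, (frame, (src_ins, src_side)) in sides.items():
            ins = by_id.loc[src_ins]
            r1_template = _frame_read(design, bc1, bc2, frame, read_len)
            for _ in range(depth_per_side):
                flank_len = int(rng.integers(flank_min, flank_max + 1))
                r2 = _flank_read2(state.genome, ins["allele"], ins["chrom"],
                                  int(ins["pos"]), src_side, flank_len)
                if r2 is None:
                    continue
                rows.append((
                    f"ivt{rid:08d}",
                    _mutate(rng, r1_template, err_rate),
                    _mutate(rng, r2, err_rate),
                    random_dna(rng, 10),
                    source_id, side, frame, ins["chrom"], int(ins["pos"]),
                    ins["allele"],
                ))
                rid += 1

    if include_insertions:
        for _, ins in state.insertions.iterrows():
            iid = ins["insertion_id"]
            emit(iid, ins["bc1"], ins["bc2"],
                 left_like_top=ins["orientation"] == TOP,
                 left_src=(iid, "left"), right_src=(iid, "right"))
    if include_derivatives:
        for _, dv in state.detectable_derivatives().iterrows():
            emit(dv["deriv_id"], dv["bc1"], dv["bc2"],
                 left_like_top=dv["left_cs"] == "CS2",
                 left_src=(dv["left_src_ins"], dv["left_src_side"]),
                 right_src=(dv["right_src_ins"], dv["right_src_side"]))
    return pd.DataFrame(rows, columns=IVT_READ_COLUMNS)


# --------------------------------------------------------------------------
# bulk amplicon emission
# --------------------------------------------------------------------------

AMPLICON_READ_COLUMNS = ["read_id", "bc1", "bc2", "umi", "amplicon_type",
                         "source_id", "is_chimera"]


def emit_amplicon_reads(
    cassettes: pd.DataFrame,
    dialect: str = "2-primer",
    molecules_per_cassette: int = 5,
    umis_per_molecule: int = 2,
    chimera_rate: float = 0.0,
    seed: int = 0,
    umi_len: int = 10,
) -> pd.DataFrame:
    """Emit UMI-tagged amplicon reads for a set of detectable cassettes.

    ``cassettes`` needs columns ``source_id, bc1, bc2`` (use
    :func:`parental_cassettes` / :func:`post_cre_cassettes`). Only cassettes
    with one CS2-side and one CS1-side barcode can be listed here — products
    with the same capture sequence on both sides are suppressed during PCR
    and never template an amplicon. In the 4-primer dialect every cassette
    yields both amplicon types, each with its own UMIs. Chimeric reads swap
    BC2 with a co-amplified cassette at ``chimera_rate``.
    """
    if dialect not in ("2-primer", "4-primer"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if not 0 <= chimera_rate <= 1:
        raise ValueError("chimera_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    bc2_pool = cassettes["bc2"].to_numpy()
    types = ["CS2-side", "CS1-side"] if dialect == "4-primer" else ["NA"]
    rows: list[tuple] = []
    rid = 0
    for _, cas in cassettes.iterrows():
        for amp_type in types:
            for _mol in range(molecules_per_cassette):
                for _u in range(umis_per_molecule):
                    umi = random_dna(rng, umi_len)
                    bc2 = cas["bc2"]
                    chimera = bool(len(bc2_pool) > 1
                                   and rng.random() < chimera_rate)
                    if chimera:
                        while True:
                            other = bc2_pool[rng.integers(len(bc2_pool))]
                            if other != bc2:
                                bc2 = other
                                break
                    rows.append((f"amp{rid:08d}", cas["bc1"], bc2, umi,
                                 amp_type, cas["source_id"], chimera))
                    rid += 1
    return pd.DataFrame(rows, columns=AMPLICON_READ_COLUMNS)


def parental_cassettes(state: SimState) -> pd.DataFrame:
    df = state.insertions[["insertion_id", "bc1", "bc2"]].copy()
    return df.rename(columns={"insertion_id": "source_id"})


def post_cre_cassettes(state: SimState) -> pd.DataFrame:
    """Parental cassettes plus all detectable derivative cassettes."""
    parts = [parental_cassettes(state)]
    dv = state.detectable_derivatives()
    if len(dv):
        parts.append(dv[["deriv_id", "bc1", "bc2"]]
                     .rename(columns={"deriv_id": "source_id"}))
    return pd.concat(parts, ignore_index=True)


# --------------------------------------------------------------------------
# single-cell emission
# --------------------------------------------------------------------------

SC_READ_COLUMNS = ["read_id", "cell_bc", "umi", "bc1", "bc2", "capture_side",
                   "read_count", "is_ambient", "source_cell_truth"]
CELL_TRUTH_COLUMNS = ["cell_bc", "clone_ids", "event_ids", "is_doublet"]
QC_COLUMNS = ["cell_bc", "transcriptome_umi", "mito_pct", "doublet_score"]


def emit_t7_single_cell_reads(
    state: SimState,
    n_cells: int = 2000,
    capture_rate: float = 0.7,
    umi_depth: float = 3.0,
    ambient_rate: float = 0.02,
    doublet_rate: float = 0.03,
    seed: int = 0,
    cells_per_event: int = 1,
    cell_bc_len: int = 16,
    umi_len: int = 12,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[str]]:
    """Emit single-cell T7 feature records with dropout, ambient and doublets.

    Each cell belongs to one clone (two for doublets) and carries its
    clone's cassettes; each recombination event is placed in
    ``cells_per_event`` cells of its clone, where the two parental cassettes
    are replaced by the event's detectable products. Each cassette pair is
    captured with ``capture_rate``; captured pairs receive
    Poisson(``umi_depth``) UMIs split across the two capture sides. Ambient
    records are drawn from the pooled population abundance so that their
    read fraction is ``ambient_rate``.

    Returns ``(records, cell_truth, qc_table, cell_whitelist)``.
    """
    if not 0 <= capture_rate <= 1:
        raise ValueError("capture_rate must be in [0, 1]")
    if not 0 <= doublet_rate <= 1:
        raise ValueError("doublet_rate must be in [0, 1]")
    if not 0 <= ambient_rate < 1:
        raise ValueError("ambient_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    clones = sorted(state.insertions["clone_id"].unique())
    by_clone = {c: sub for c, sub in state.insertions.groupby("clone_id")}

    cell_bcs: list[str] = []
    seen = set()
    while len(cell_bcs) < n_cells:
        bc = random_dna(rng, cell_bc_len)
        if bc not in seen:
            seen.add(bc)
            cell_bcs.append(bc)

    cell_clones: list[list[str]] = []
    for _ in range(n_cells):
        picked = [clones[rng.integers(len(clones))]]
        if rng.random() < doublet_rate:
            others = [c for c in clones if c != picked[0]]
            if others:
                picked.append(others[rng.integers(len(others))])
        cell_clones.append(picked)

    clone_cells: dict[str, list[int]] = {c: [] for c in clones}
    for i, picked in enumerate(cell_clones):
        for c in picked:
            clone_cells[c].append(i)

    # assign events to cells of their clone
    cell_events: dict[int, list[str]] = {i: [] for i in range(n_cells)}
    if len(state.events):
        for _, ev in state.events.iterrows():
            host = clone_cells.get(ev["clone_id"], [])
            if not host:
                continue
            k = min(cells_per_event, len(host))
            for ci in rng.choice(len(host), size=k, replace=False):
                cell_events[host[int(ci)]].append(ev["event_id"])

    derivs = state.derivatives.set_index("event_id") if len(state.derivatives) else None
    events_ix = state.events.set_index("event_id") if len(state.events) else None

    rows: list[tuple] = []
    rid = 0
    ambient_pool: list[tuple[str, str]] = []
    for i, cbc in enumerate(cell_bcs):
        pairs: list[tuple[str, str]] = []
        consumed: set[str] = set()
        for ev_id in cell_events[i]:
            ev = events_ix.loc[ev_id]
            consumed.update([ev["ins_a"], ev["ins_b"]])
            prods = derivs.loc[[ev_id]]
            for _, dv in prods.iterrows():
                if dv["detectable"]:
                    pairs.append((dv["bc1"], dv["bc2"]))
        for clone in cell_clones[i]:
            sub = by_clone[clone]
            keep = sub[~sub["insertion_id"].isin(consumed)]
            pairs.extend(zip(keep["bc1"], keep["bc2"]))
        ambient_pool.extend(pairs)  # population abundance, rearranged incl.
        for bc1, bc2 in pairs:
            if rng.random() >= capture_rate:
                continue
            n_umi = rng.poisson(umi_depth)
            for _u in range(n_umi):
                side = "CS2" if rng.random() < 0.5 else "CS1"
                rows.append((f"sc{rid:08d}", cbc, random_dna(rng, umi_len),
                             bc1, bc2, side, int(rng.poisson(2)) + 1,
                             False, i))
                rid += 1

    # ambient contamination from the pooled population
    if ambient_rate > 0 and rows:
        n_real_reads = sum(r[6] for r in rows)
        n_ambient = rng.binomial(n_real_reads,
                                 ambient_rate / (1.0 - ambient_rate))
        pool = ambient_pool
        for _ in range(n_ambient):
            bc1, bc2 = pool[rng.integers(len(pool))]
            rows.append((f"sc{rid:08d}", cell_bcs[rng.integers(n_cells)],
                         random_dna(rng, umi_len), bc1, bc2,
                         "CS2" if rng.random() < 0.5 else "CS1",
                         1, True, -1))
            rid += 1

    records = pd.DataFrame(rows, columns=SC_READ_COLUMNS)
    truth = pd.DataFrame({
        "cell_bc": cell_bcs,
        "clone_ids": [",".join(c) for c in cell_clones],
        "event_ids": [",".join(cell_events[i]) for i in range(n_cells)],
        "is_doublet": [len(c) > 1 for c in cell_clones],
    })
    is_doublet = truth["is_doublet"].to_numpy()
    qc = pd.DataFrame({
        "cell_bc": cell_bcs,
        "transcriptome_umi": rng.lognormal(8.0, 0.5, n_cells).astype(int),
        "mito_pct": np.clip(rng.normal(6.0, 2.0, n_cells), 0.0, 100.0),
        "doublet_score": np.where(
            is_doublet, rng.uniform(0.2, 0.9, n_cells),
            rng.uniform(0.0, 0.3, n_cells)),
    })
    return records, truth, qc, cell_bcs


def sc_read2_sequence(design: CassetteDesign, bc1: str, bc2: str,
                      capture_side: str, read_len: int = 96) -> str:
    """Single-cell read-2 sequence for one captured transcript.

    CS2-side capture reads the cassette top strand (TGAGC anchor at
    positions 15–19, 1-based); CS1-side capture reads the bottom strand
    (AAAGC anchor in the same window), so the second barcode's GTTAT anchor
    lands at position 69 in both layouts.
    """
    frame = TOP if capture_side == "CS2" else BOTTOM
    return _frame_read(design, bc1, bc2, frame, read_len)


# --------------------------------------------------------------------------
# truth I/O
# --------------------------------------------------------------------------

_TRUTH_FILES = {
    "insertions": INSERTION_COLUMNS,
    "events": EVENT_COLUMNS,
    "derivatives": DERIV_COLUMNS,
}


def write_truth(state: SimState, out_dir: str | Path) -> dict[str, Path]:
    """Write truth tables as headered TSVs (lossless round trip)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, cols in _TRUTH_FILES.items():
        df = getattr(state, name)
        p = out / f"truth_{name}.tsv"
        df.to_csv(p, sep="\t", index=False, columns=list(cols))
        paths[name] = p
    var_p = out / "truth_variants.tsv"
    state.genome.variants.to_csv(var_p, sep="\t", index=False)
    paths["variants"] = var_p
    return paths


_TRUTH_DTYPES = {
    "pos": np.int64, "size": np.int64, "detectable": bool,
    "junction_pos": np.int64,
}


def read_truth(out_dir: str | Path) -> dict[str, pd.DataFrame]:
    out = Path(out_dir)
    tables: dict[str, pd.DataFrame] = {}
    for name in list(_TRUTH_FILES) + ["variants"]:
        p = out / f"truth_{name}.tsv"
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
        for col, dt in _TRUTH_DTYPES.items():
            if col in df.columns:
                if dt is bool:
                    df[col] = df[col].map({"True": True, "False": False})
                else:
                    df[col] = df[col].astype(dt)
        if name == "variants" and "pos" in df.columns and len(df):
            df["pos"] = df["pos"].astype(np.int64)
        tables[name] = df
    return tables


def iter_fastq_pairs(reads: pd.DataFrame) -> Iterable[tuple[str, str, str]]:
    """Yield (read_id, read1, read2) for FASTQ serialization."""
    for row in reads.itertuples(index=False):
        yield row.read_id, row.read1, row.read2
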