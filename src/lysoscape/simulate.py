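"""Synthetic lysogen cohorts with planted prophages and ground truth.

The generator emulates the statistical structure a compositional prophage
detector relies on, without any real biological sequence:

* a host backbone of random sequence at a target GC, carrying synthetic CDS
  blocks (~900 bp genes in alternating-strand blocks);
* prophage cassettes with shorter genes (~600 bp) predominantly on one
  strand, a sequence enriched for a set of marker k-mers, modest GC/AT-skew
  deviation from the backbone, and an exact direct repeat (att site) at both
  ends;
* cassette lengths drawn from a log-normal mixture (single component peaked
  near 20 kbp by default), planted to a target genomic prophage density
  (default 2.4%) in a configurable fraction of lysogens (default 94%);
* PATRIC/GTDB-style metadata columns (isolation date, country, lineage,
  MAG flag) and an exact ground-truth table for recovery testing.

All randomness flows from ``SyntheticSpec.seed`` through per-genome
``numpy`` seed sequences; two runs with an equal spec are bit-identical.
Layout and planting draws are separated from sequence realisation, so
coordinate-only cohorts (``sequences=False``) share their ground truth with
fully realised ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genomes import GenomeRecord, OrfFeature, write_genbank

__all__ = [
    "SyntheticSpec",
    "CohortTruth",
    "generate_marker_kmers",
    "generate_backbone",
    "generate_prophage",
    "plant_prophages",
    "mag_degrade",
    "generate_cohort",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_COUNTRIES = (
    "USA",
    "China",
    "United Kingdom",
    "Australia",
    "Germany",
    "Japan",
    "Brazil",
    "South Africa",
)

DEFAULT_TAXA = (
    "d__Bacteria;p__Pseudomonadota;c__Gammaproteobacteria;o__Enterobacterales;"
    "f__Enterobacteriaceae;g__Escherichia;s__Escherichia coli",
    "d__Bacteria;p__Pseudomonadota;c__Gammaproteobacteria;o__Enterobacterales;"
    "f__Enterobacteriaceae;g__Salmonella;s__Salmonella enterica",
    "d__Bacteria;p__Bacillota;c__Bacilli;o__Lactobacillales;"
    "f__Streptococcaceae;g__Streptococcus;s__Streptococcus pneumoniae",
    "d__Bacteria;p__Bacillota;c__Bacilli;o__Bacillales;"
    "f__Listeriaceae;g__Listeria;s__Listeria monocytogenes",
    "d__Bacteria;p__Campylobacterota;c__Campylobacteria;o__Campylobacterales;"
    "f__Campylobacteraceae;g__Campylobacter;s__Campylobacter jejuni",
    "d__Bacteria;p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;"
    "f__Bacteroidaceae;g__Bacteroides;s__Bacteroides fragilis",
    "d__Bacteria;p__Actinomycetota;c__Actinomycetes;o__Mycobacteriales;"
    "f__Mycobacteriaceae;g__Mycobacterium;s__Mycobacterium tuberculosis",
    "d__Bacteria;p__Pseudomonadota;c__Alphaproteobacteria;o__Pelagibacterales;"
    "f__Pelagibacteraceae;g__Pelagibacter;s__Pelagibacter ubique",
)

MIN_GENE_LEN = 300  #: shortest synthetic gene, bp
MIN_CASSETTE_LEN = 4000  #: shortest plantable prophage, bp
EDGE_MARGIN = 2500  #: planted regions stay this far from contig edges, bp


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic lysogen cohort.

    Defaults follow the landscape the analysis targets: genome length mode
    2.3 Mbp, prophage length mode 20 kbp, genomic prophage density 2.4%,
    and a 94% lysogen fraction.
    """

    n_genomes: int = 1
    genome_len_mode: int = 2_300_000
    genome_len_spread: int = 200_000
    genome_len_range: tuple[int, int] | None = None  # uniform draw overrides mode/spread
    backbone_gc: float = 0.50
    prophage_len_mode: int = 20_000
    prophage_len_sd: int = 8_000
    prophage_len_components: tuple[tuple[float, float, float], ...] | None = None
    target_density: float = 0.024
    lysogen_fraction: float = 0.94
    marker_kmer_count: int = 256
    kmer_k: int = 12
    # The marker vocabulary plays the role of a shared phage-gene database:
    # cohorts with the same marker_seed share it, whatever their cohort seed.
    marker_seed: int = 1042
    att_repeat_len: int = 12
    marker_spacing: int = 150
    phage_annotation_rate: float = 0.25
    mag_fraction: float = 0.0
    mag_loss_prob: float = 2.0 / 3.0
    year_range: tuple[int, int] = (1995, 2022)
    country_pool: tuple[str, ...] = DEFAULT_COUNTRIES
    taxon_pool: tuple[str, ...] = DEFAULT_TAXA
    seed: int = 0

    def __post_init__(self):
        for name in ("backbone_gc",):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        for name in ("target_density", "lysogen_fraction", "mag_fraction",
                     "phage_annotation_rate", "mag_loss_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.prophage_len_mode < 5 * MIN_GENE_LEN:
            raise ValueError("prophage_len_mode below the minimum viable region (5 genes)")
        if self.components is not None:
            w = sum(c[0] for c in self.components)
            if abs(w - 1.0) > 1e-9:
                raise ValueError(f"mixture weights must sum to 1, got {w}")

    @property
    def components(self) -> tuple[tuple[float, float, float], ...]:
        if self.prophage_len_components is not None:
            return tuple(self.prophage_len_components)
        return ((1.0, float(self.prophage_len_mode), float(self.prophage_len_sd)),)

    def marker_set(self) -> list[str]:
        """The marker k-mer vocabulary shared by cohorts with this marker_seed."""
        return generate_marker_kmers(self.marker_kmer_count, self.kmer_k, self.marker_seed)


@dataclass
class CohortTruth:
    """Ground truth for a synthetic cohort.

    ``regions``: one row per planted prophage (accession, contig_id, start,
    end, length, component), coordinates 0-based half-open in the emitted
    genome.  ``genomes``: one row per genome (accession, genome_bp = host bp
    excluding prophages, prophage_bp, n_prophages, true_density, is_lysogen).
    """

    regions: pd.DataFrame
    genomes: pd.DataFrame

    @staticmethod
    def empty() -> "CohortTruth":
        return CohortTruth(
            regions=pd.DataFrame(
                columns=["accession", "contig_id", "start", "end", "length", "component"]
            ),
            genomes=pd.DataFrame(
                columns=[
                    "accession", "genome_bp", "prophage_bp", "n_prophages",
                    "true_density", "is_lysogen",
                ]
            ),
        )


# ---------------------------------------------------------------------------
# sequence primitives

def _random_seq(rng: np.random.Generator, length: int, gc: float,
                gc_skew: float = 0.0, at_skew: float = 0.0) -> np.ndarray:
    """Random base codes (0..3 = ACGT) at a target composition."""
    p_g = gc / 2 * (1 + gc_skew)
    p_c = gc / 2 * (1 - gc_skew)
    p_a = (1 - gc) / 2 * (1 + at_skew)
    p_t = (1 - gc) / 2 * (1 - at_skew)
    return rng.choice(4, size=length, p=[p_a, p_c, p_g, p_t]).astype(np.uint8)


def codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _kmer_to_codes(kmer: str) -> np.ndarray:
    lut = {"A": 0, "C": 1, "G": 2, "T": 3}
    return np.array([lut[b] for b in kmer], dtype=np.uint8)


def generate_marker_kmers(count: int, k: int, seed) -> list[str]:
    """A deterministic set of distinct marker k-mers."""
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < count:
        km = codes_to_seq(rng.integers(0, 4, size=k).astype(np.uint8))
        if km not in seen:
            seen.add(km)
            out.append(km)
    return out


# ---------------------------------------------------------------------------
# gene layouts (coordinate-only; shared by plan and full modes)

def _host_gene_layout(rng: np.random.Generator, length: int) -> list[tuple[int, int, int]]:
    """Host CDS blocks: ~900 bp genes, alternating-strand blocks of ~5."""
    genes = []
    pos = int(rng.integers(50, 250))
    strand = 1 if rng.random() < 0.5 else -1
    block_left = int(rng.integers(3, 8))
    while True:
        glen = int(np.clip(rng.normal(900, 150), MIN_GENE_LEN, 3000))
        glen -= glen % 3
        if pos + glen > length - 50:
            break
        genes.append((pos, pos + glen, strand))
        pos += glen + int(np.clip(rng.normal(120, 40), 20, 500))
        block_left -= 1
        if block_left == 0:
            strand = -strand
            block_left = int(rng.integers(3, 8))
    return genes


def _phage_gene_layout(
    rng: np.random.Generator, length: int, att_len: int
) -> list[tuple[int, int, int]]:
    """Prophage CDS: ~600 bp genes, >=80% on a common strand."""
    cassette_strand = 1 if rng.random() < 0.5 else -1
    genes = []
    pos = att_len + int(rng.integers(10, 60))
    while True:
        glen = int(np.clip(rng.normal(600, 100), MIN_GENE_LEN, 1800))
        glen -= glen % 3
        if pos + glen > length - att_len - 10:
            break
        strand = cassette_strand if rng.random() < 0.9 else -cassette_strand
        genes.append((pos, pos + glen, strand))
        pos += glen + int(np.clip(rng.normal(60, 20), 10, 200))
    return genes


# ---------------------------------------------------------------------------
# public sequence-level operations

def generate_backbone(length: int, gc: float, seed) -> tuple[str, list[OrfFeature]]:
    """A host-like contig: random sequence at GC ``gc`` with synthetic CDS.

    Returns the sequence and its CDS features (contig_id left empty for the
    caller to assign).
    """
    if length <= 0:
        raise ValueError(f"backbone length must be positive, got {length}")
    if length < 5000:
        raise ValueError(f"backbone length must be >= 5000 bp, got {length}")
    if not 0 < gc < 1:
        raise ValueError(f"gc must be in (0,1), got {gc}")
    ss = np.random.SeedSequence(seed)
    rng_layout, rng_seq = (np.random.default_rng(s) for s in ss.spawn(2))
    layout = _host_gene_layout(rng_layout, length)
    codes = _random_seq(rng_seq, length, gc)
    features = [
        OrfFeature("", s, e, st, "hypothetical protein") for s, e, st in layout
    ]
    return codes_to_seq(codes), features


_PHAGE_PRODUCTS = (
    "phage integrase",
    "phage major capsid protein",
    "phage tail fiber protein",
    "phage terminase large subunit",
    "phage portal protein",
    "prophage repressor",
)


@dataclass
class ProphageCassette:
    """A realised prophage insert: sequence, genes, and the att repeat."""

    seq: str
    genes: list[OrfFeature]  # coordinates relative to cassette start
    att_len: int

    @property
    def length(self) -> int:
        return len(self.seq)


def generate_prophage(
    length: int,
    marker_set: list[str],
    seed,
    gc: float = 0.50,
    att_repeat_len: int = 12,
    marker_spacing: int = 150,
    phage_annotation_rate: float = 0.25,
) -> ProphageCassette:
    """A prophage cassette with detector-visible compositional contrast.

    The cassette carries genes predominantly on one strand, marker k-mers
    substituted roughly every ``marker_spacing`` bp, skewed base composition,
    and an exact direct repeat of ``att_repeat_len`` bp at both ends.
    """
    if not marker_set:
        raise ValueError("marker_set must be non-empty")
    min_len = 5 * MIN_GENE_LEN + 2 * att_repeat_len + 200
    if length < min_len:
        raise ValueError(
            f"cassette length {length} cannot host 5 genes (needs >= {min_len} bp)"
        )
    ss = np.random.SeedSequence(seed)
    rng_layout, rng_seq, rng_mark, rng_annot = (np.random.default_rng(s) for s in ss.spawn(4))
    layout = _phage_gene_layout(rng_layout, length, att_repeat_len)
    codes = _random_seq(rng_seq, length, gc, gc_skew=0.25, at_skew=-0.20)

    # plant marker k-mers by substitution at a fixed mean spacing
    k = len(marker_set[0])
    n_markers = max(1, int(length // marker_spacing))
    starts = rng_mark.integers(att_repeat_len, length - att_repeat_len - k, size=n_markers)
    picks = rng_mark.integers(0, len(marker_set), size=n_markers)
    for s, p in zip(starts, picks):
        codes[s : s + k] = _kmer_to_codes(marker_set[p])

    # exact direct repeat at both ends
    codes[-att_repeat_len:] = codes[:att_repeat_len]

    genes = []
    for s, e, st in layout:
        if rng_annot.random() < phage_annotation_rate:
            product = _PHAGE_PRODUCTS[int(rng_annot.integers(0, len(_PHAGE_PRODUCTS)))]
        else:
            product = "hypothetical protein"
        genes.append(OrfFeature("", s, e, st, product))
    return ProphageCassette(seq=codes_to_seq(codes), genes=genes, att_len=att_repeat_len)


# ---------------------------------------------------------------------------
# length model

def _lognormal_sigma(mode: float, sd: float) -> float:
    """Sigma of a log-normal with the given mode and standard deviation."""

    def f(sig):
        return mode * math.exp(1.5 * sig * sig) * math.sqrt(math.expm1(sig * sig)) - sd

    return brentq(f, 1e-6, 3.0)


def draw_prophage_lengths(
    rng: np.random.Generator,
    components: tuple[tuple[float, float, float], ...],
    size: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw cassette lengths (and component ids) from the log-normal mixture."""
    weights = np.array([c[0] for c in components])
    comp_idx = rng.choice(len(components), size=size, p=weights / weights.sum())
    out = np.empty(size)
    for i, ci in enumerate(comp_idx):
        _, mode, sd = components[ci]
        sigma = _lognormal_sigma(mode, sd)
        mu = math.log(mode) + sigma * sigma
        val = rng.lognormal(mu, sigma)
        tries = 0
        while not (MIN_CASSETTE_LEN <= val <= 150_000) and tries < 50:
            val = rng.lognormal(mu, sigma)
            tries += 1
        out[i] = np.clip(val, MIN_CASSETTE_LEN, 150_000)
    return out.astype(np.int64), comp_idx.astype(np.int64)


def _plan_lengths(
    rng: np.random.Generator, spec: SyntheticSpec, host_bp: int
) -> tuple[np.ndarray, np.ndarray]:
    """Cassette lengths totalling the target density within +-20% relative."""
    if spec.target_density <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    target = spec.target_density * host_bp
    if target < MIN_CASSETTE_LEN:
        raise ValueError(
            f"target density {spec.target_density} infeasible for host of {host_bp} bp: "
            f"target prophage bp {target:.0f} is below the minimum cassette of "
            f"{MIN_CASSETTE_LEN} bp"
        )
    lengths: list[int] = []
    comps: list[int] = []
    total = 0
    while total < 0.9 * target:
        ln, ci = draw_prophage_lengths(rng, spec.components, 1)
        ln, ci = int(ln[0]), int(ci[0])
        if total + ln <= 1.15 * target:
            lengths.append(ln)
            comps.append(ci)
            total += ln
        elif total >= 0.85 * target:
            break
        else:
            # remaining gap too small for this draw: shrink it to fit
            ln = int(np.clip(target - total, MIN_CASSETTE_LEN, None))
            lengths.append(ln)
            comps.append(ci)
            total += ln
    return np.array(lengths, dtype=np.int64), np.array(comps, dtype=np.int64)


# ---------------------------------------------------------------------------
# planting

def _insertion_gaps(features: list[OrfFeature], contig_len: int) -> np.ndarray:
    """Candidate insertion points: midpoints of intergenic gaps."""
    if not features:
        return np.arange(EDGE_MARGIN, max(contig_len - EDGE_MARGIN, EDGE_MARGIN) + 1, 1000)
    pts = []
    prev_end = 0
    for f in sorted(features, key=lambda f: f.start):
        if f.start > prev_end:
            pts.append((prev_end + f.start) // 2)
        prev_end = max(prev_end, f.end)
    if contig_len > prev_end:
        pts.append((prev_end + contig_len) // 2)
    pts = np.array(pts, dtype=np.int64)
    return pts[(pts >= EDGE_MARGIN) & (pts <= contig_len - EDGE_MARGIN)]


MIN_SEPARATION = 5000  #: minimum distance between planted cassettes, bp


def _choose_insertions(
    rng: np.random.Generator, gaps: np.ndarray, n: int
) -> np.ndarray | None:
    """Pick ``n`` well-separated insertion points from the gap candidates."""
    if len(gaps) < n:
        return None
    for _ in range(200):
        picks = np.sort(rng.choice(gaps, size=n, replace=False))
        if n == 1 or np.min(np.diff(picks)) >= MIN_SEPARATION:
            return picks
    return None


def plant_prophages(
    genome: GenomeRecord, spec: SyntheticSpec, seed
) -> tuple[GenomeRecord, pd.DataFrame]:
    """Insert prophage cassettes into a genome to the spec's target density.

    Cassettes are placed in intergenic gaps of the largest contig, at least
    2.5 kbp from contig edges and 5 kbp apart, until the summed cassette
    length is within +-20% (relative) of ``target_density`` x host bp.
    Returns the modified genome and its truth rows.
    """
    if not any(len(seq) >= 5000 for _, seq in genome.contigs):
        raise ValueError(f"{genome.accession}: no contig >= 5000 bp to plant into")
    ss = np.random.SeedSequence(seed)
    rng_plan, rng_seq = (np.random.default_rng(s) for s in ss.spawn(2))
    marker_set = spec.marker_set()
    host_bp = genome.total_bp
    lengths, comps = _plan_lengths(rng_plan, spec, host_bp)
    truth_cols = ["accession", "contig_id", "start", "end", "length", "component"]
    if len(lengths) == 0:
        return genome, pd.DataFrame(columns=truth_cols)

    # plant everything into the largest contig
    cid, cseq = max(genome.contigs, key=lambda c: len(c[1]))
    feats = genome.cds_on(cid)
    gaps = _insertion_gaps(feats, len(cseq))
    offsets = _choose_insertions(rng_plan, gaps, len(lengths))
    if offsets is None:
        raise ValueError(
            f"{genome.accession}: target density {spec.target_density} infeasible: "
            f"cannot place {len(lengths)} cassettes in {len(gaps)} intergenic gaps"
        )

    cassettes = [
        generate_prophage(
            int(ln),
            marker_set,
            s,
            gc=spec.backbone_gc,
            att_repeat_len=spec.att_repeat_len,
            marker_spacing=spec.marker_spacing,
            phage_annotation_rate=spec.phage_annotation_rate,
        )
        for ln, s in zip(lengths, rng_seq.integers(0, 2**31 - 1, size=len(lengths)))
    ]

    new_seq_parts = []
    new_feats: list[OrfFeature] = []
    truth_rows = []
    shift = 0
    prev = 0
    other_feats = [f for f in genome.cds if f.contig_id != cid]
    for off, cass, comp in zip(offsets, cassettes, comps):
        new_seq_parts.append(cseq[prev:off])
        start = off + shift
        new_seq_parts.append(cass.seq)
        for g in cass.genes:
            new_feats.append(
                OrfFeature(cid, start + g.start, start + g.end, g.strand, g.annotation)
            )
        truth_rows.append(
            dict(
                accession=genome.accession,
                contig_id=cid,
                start=start,
                end=start + cass.length,
                length=cass.length,
                component=int(comp),
            )
        )
        shift += cass.length
        prev = off
    new_seq_parts.append(cseq[prev:])
    new_cseq = "".join(new_seq_parts)

    # shift host features past each insertion point
    for f in feats:
        fshift = int(np.sum(lengths[offsets <= f.start]))
        new_feats.append(
            OrfFeature(cid, f.start + fshift, f.end + fshift, f.strand, f.annotation)
        )
    new_contigs = [(c, new_cseq if c == cid else s) for c, s in genome.contigs]
    rec = GenomeRecord(
        accession=genome.accession,
        contigs=new_contigs,
        cds=sorted(other_feats + new_feats, key=lambda f: (f.contig_id, f.start)),
        source=genome.source,
    )
    return rec, pd.DataFrame(truth_rows, columns=truth_cols)


def mag_degrade(
    genome: GenomeRecord | None,
    truth_regions: pd.DataFrame,
    loss_prob: float,
    seed,
) -> tuple[GenomeRecord | None, pd.DataFrame]:
    """Emulate MAG assembly loss of prophages.

    Each planted prophage is excised with probability ``loss_prob``; the
    host contig is split at the excision point, mimicking binning pipelines
    that fail to incorporate phage-like contigs.  Works on a realised genome
    (sequence + features updated) or, with ``genome=None``, on the truth
    table alone.  Returns the degraded genome and the updated truth rows.
    """
    if not 0 <= loss_prob <= 1:
        raise ValueError(f"loss_prob must be in [0,1], got {loss_prob}")
    rng = np.random.default_rng(seed)
    regions = truth_regions.sort_values(["contig_id", "start"]).reset_index(drop=True)
    lost = rng.random(len(regions)) < loss_prob
    if len(regions) == 0 or loss_prob == 0:
        return genome, regions
    if genome is None:
        return None, regions[~lost].reset_index(drop=True)

    new_contigs: list[tuple[str, str]] = []
    new_feats: list[OrfFeature] = []
    new_rows = []
    for cid, cseq in genome.contigs:
        sub = regions[regions["contig_id"] == cid]
        sub_lost = lost[sub.index.to_numpy()] if len(sub) else np.empty(0, dtype=bool)
        cuts = sub[sub_lost] if len(sub) else sub
        if len(cuts) == 0:
            new_contigs.append((cid, cseq))
            for f in genome.cds_on(cid):
                new_feats.append(f)
            for _, r in sub.iterrows():
                new_rows.append({**r.to_dict(), "contig_id": cid})
            continue
        # split the contig at each excised cassette
        bounds = [0] + [int(v) for se in zip(cuts["start"], cuts["end"]) for v in se] + [len(cseq)]
        seg_id = 0
        for i in range(0, len(bounds) - 1, 2):
            seg_start, seg_end = bounds[i], bounds[i + 1]
            if seg_end - seg_start <= 0:
                continue
            part_id = f"{cid}_p{seg_id}"
            seg_id += 1
            new_contigs.append((part_id, cseq[seg_start:seg_end]))
            for f in genome.cds_on(cid):
                if f.start >= seg_start and f.end <= seg_end:
                    new_feats.append(
                        OrfFeature(part_id, f.start - seg_start, f.end - seg_start,
                                   f.strand, f.annotation)
                    )
            keep = sub[(~sub_lost) & (sub["start"] >= seg_start) & (sub["end"] <= seg_end)]
            for _, r in keep.iterrows():
                row = r.to_dict()
                row["contig_id"] = part_id
                row["start"] = int(r["start"]) - seg_start
                row["end"] = int(r["end"]) - seg_start
                new_rows.append(row)
    rec = GenomeRecord(
        accession=genome.accession, contigs=new_contigs, cds=new_feats, source="MAG"
    )
    return rec, pd.DataFrame(new_rows, columns=regions.columns)


# ---------------------------------------------------------------------------
# cohort generation

def _genome_length(rng: np.random.Generator, spec: SyntheticSpec) -> int:
    if spec.genome_len_range is not None:
        lo, hi = spec.genome_len_range
        return int(rng.integers(lo, hi + 1))
    ln = rng.normal(spec.genome_len_mode, spec.genome_len_spread)
    return int(np.clip(ln, 500_000, 15_000_000))


def generate_cohort(
    spec: SyntheticSpec,
    out_dir: str | Path | None = None,
    sequences: bool = True,
) -> tuple[list[GenomeRecord] | None, pd.DataFrame, CohortTruth]:
    """Generate a synthetic lysogen cohort.

    Returns ``(records, metadata, truth)``.  With ``sequences=False`` only
    coordinates and metadata are drawn (records is None) — the truth tables
    are identical to a full run with the same spec.  With ``out_dir`` set,
    GenBank files, ``metadata.tsv``, ``truth_regions.tsv``,
    ``truth_genomes.tsv`` and ``markers.txt`` are written there.
    """
    if spec.n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    if not spec.country_pool or not spec.taxon_pool:
        raise ValueError("country_pool and taxon_pool must be non-empty")
    master = np.random.SeedSequence(spec.seed)
    ss_meta, *ss_genomes = master.spawn(1 + spec.n_genomes)
    marker_set = spec.marker_set()
    rng_meta = np.random.default_rng(ss_meta)

    records: list[GenomeRecord] | None = [] if sequences else None
    meta_rows = []
    region_frames = []
    genome_rows = []
    for i in range(spec.n_genomes):
        acc = f"SYN{i:06d}.1"
        ss = ss_genomes[i]
        ss_layout, ss_plant, ss_seq, ss_mag = ss.spawn(4)
        rng_layout = np.random.default_rng(ss_layout)
        rng_plant = np.random.default_rng(ss_plant)

        glen = _genome_length(rng_layout, spec)
        host_layout = _host_gene_layout(rng_layout, glen)
        is_lysogen = rng_meta.random() < spec.lysogen_fraction
        is_mag = rng_meta.random() < spec.mag_fraction
        country = str(rng_meta.choice(list(spec.country_pool)))
        lineage = str(rng_meta.choice(list(spec.taxon_pool)))
        year = int(rng_meta.integers(spec.year_range[0], spec.year_range[1] + 1))
        month = int(rng_meta.integers(1, 13))
        day = int(rng_meta.integers(1, 29))
        iso_date = f"{year:04d}-{month:02d}-{day:02d}"

        # planting plan (shared between plan and full modes)
        if is_lysogen and spec.target_density > 0:
            lengths, comps = _plan_lengths(rng_plant, spec, glen)
            cid = "contig_1"
            feats0 = [OrfFeature(cid, s, e, st) for s, e, st in host_layout]
            gaps = _insertion_gaps(feats0, glen)
            offsets = _choose_insertions(rng_plant, gaps, len(lengths))
            if offsets is None:
                raise ValueError(
                    f"{acc}: target density infeasible for genome of {glen} bp"
                )
        else:
            lengths = np.empty(0, dtype=np.int64)
            comps = np.empty(0, dtype=np.int64)
            offsets = np.empty(0, dtype=np.int64)
            cid = "contig_1"

        shift = np.cumsum(np.concatenate([[0], lengths[:-1]]))
        truth = pd.DataFrame(
            dict(
                accession=acc,
                contig_id=cid,
                start=offsets + shift,
                end=offsets + shift + lengths,
                length=lengths,
                component=comps,
            )
        )

        rec = None
        if sequences:
            rng_seq = np.random.default_rng(ss_seq)
            bb_codes = _random_seq(rng_seq, glen, spec.backbone_gc)
            cassettes = [
                generate_prophage(
                    int(ln), marker_set, cs,
                    gc=spec.backbone_gc,
                    att_repeat_len=spec.att_repeat_len,
                    marker_spacing=spec.marker_spacing,
                    phage_annotation_rate=spec.phage_annotation_rate,
                )
                for ln, cs in zip(
                    lengths, rng_seq.integers(0, 2**31 - 1, size=len(lengths))
                )
            ]
            parts = []
            feats: list[OrfFeature] = []
            prev = 0
            for off, sh, cass in zip(offsets, shift, cassettes):
                parts.append(codes_to_seq(bb_codes[prev:off]))
                parts.append(cass.seq)
                for g in cass.genes:
                    feats.append(
                        OrfFeature(cid, off + sh + g.start, off + sh + g.end,
                                   g.strand, g.annotation)
                    )
                prev = off
            parts.append(codes_to_seq(bb_codes[prev:]))
            full_seq = "".join(parts)
            for s, e, st in host_layout:
                fshift = int(np.sum(lengths[offsets <= s]))
                feats.append(OrfFeature(cid, s + fshift, e + fshift, st,
                                        "hypothetical protein"))
            rec = GenomeRecord(
                accession=acc,
                contigs=[(cid, full_seq)],
                cds=sorted(feats, key=lambda f: f.start),
                source="MAG" if is_mag else "isolate",
            )

        if is_mag:
            rec, truth = mag_degrade(rec, truth, spec.mag_loss_prob, ss_mag)

        prophage_bp = int(truth["length"].sum()) if len(truth) else 0
        genome_rows.append(
            dict(
                accession=acc,
                genome_bp=glen,
                prophage_bp=prophage_bp,
                n_prophages=len(truth),
                true_density=prophage_bp / glen,
                is_lysogen=len(truth) > 0,
            )
        )
        region_frames.append(truth)
        meta_rows.append(
            dict(
                assembly_accession=acc,
                isolation_date=iso_date,
                country=country,
                gtdb_lineage=lineage,
                is_mag=is_mag,
            )
        )
        if sequences:
            records.append(rec)

    metadata = pd.DataFrame(meta_rows)
    truth = CohortTruth(
        regions=pd.concat(region_frames, ignore_index=True)
        if region_frames
        else CohortTruth.empty().regions,
        genomes=pd.DataFrame(genome_rows),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        metadata.to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
        truth.regions.to_csv(out_dir / "truth_regions.tsv", sep="\t", index=False)
        truth.genomes.to_csv(out_dir / "truth_genomes.tsv", sep="\t", index=False)
        (out_dir / "markers.txt").write_text("\n".join(marker_set) + "\n")
        if sequences:
            gdir = out_dir / "genomes"
            gdir.mkdir(exist_ok=True)
            for rec in records:
                write_genbank(rec, gdir / f"{rec.accession}.gbff")
    return records, metadata, truth
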