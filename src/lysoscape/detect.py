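"""Compositional prophage detection.

The detector reconstructs the classic multi-step procedure: per-ORF window
features (median ORF length, same-strand run fraction, phage k-mer score,
GC- and AT-skew deviation from the genome baseline), a random-forest
classifier over those features, assembly of phage-predicted ORF runs into
candidate regions, boundary refinement by flanking direct-repeat (att)
search, and a verification step requiring phage-annotated genes or hits
from a pluggable provider (marker-k-mer lookup, or profile HMMs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .config import RunConfig
from .genomes import GenomeRecord, OrfFeature

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_COLUMNS",
    "ProphageRegion",
    "ClassifierModel",
    "call_orfs",
    "compute_skews",
    "kmer_phage_score",
    "window_metrics",
    "orf_feature_table",
    "train_classifier",
    "assemble_regions",
    "refine_boundaries",
    "verify_region",
    "detect",
    "MarkerHitProvider",
    "HmmHitProvider",
]

FEATURE_COLUMNS = (
    "median_orf_len",
    "same_strand_run",
    "phage_kmer_score",
    "gc_skew_dev",
    "at_skew_dev",
)

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class ProphageRegion:
    """A candidate prophage region (0-based half-open coordinates)."""

    contig_id: str
    start: int
    end: int
    n_genes: int
    att_repeat: tuple[int, int, int] | None = None  # (left start, right start, length)
    phage_annotated_genes: int = 0
    verified_bp_fraction: float = 0.0
    status: str = "pending"  # pending | kept | discarded
    discard_reason: str | None = None
    orf_rows: list[int] = field(default_factory=list, repr=False)

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# ORF calling (FASTA fallback; GenBank CDS features are preferred)

_STOPS = ("TAA", "TAG", "TGA")
_COMP = str.maketrans("ACGT", "TGCA")


def _orfs_one_strand(seq: str, min_orf_len: int):
    """Maximal ATG->stop ORFs in the three forward frames of ``seq``."""
    n = len(seq)
    for frame in range(3):
        last_stop = frame  # start of the open stretch in this frame
        pos = frame
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if codon in _STOPS:
                # first ATG in (last_stop, pos]
                q = last_stop
                while q < pos and seq[q : q + 3] != "ATG":
                    q += 3
                if q < pos and (pos + 3 - q) >= min_orf_len:
                    yield q, pos + 3
                last_stop = pos + 3
            pos += 3


def call_orfs(seq: str, min_orf_len: int = 90, contig_id: str = "") -> list[OrfFeature]:
    """Maximal start-to-stop open reading frames on both strands.

    An ORF runs from the first ATG after the previous in-frame stop to the
    end of the stop codon, and must be at least ``min_orf_len`` bp long.
    Returns features sorted by start coordinate.
    """
    seq = seq.upper()
    n = len(seq)
    out = []
    for s, e in _orfs_one_strand(seq, min_orf_len):
        out.append(OrfFeature(contig_id, s, e, 1, ""))
    rc = seq.translate(_COMP)[::-1]
    for s, e in _orfs_one_strand(rc, min_orf_len):
        out.append(OrfFeature(contig_id, n - e, n - s, -1, ""))
    return sorted(out, key=lambda f: (f.start, f.end))


# ---------------------------------------------------------------------------
# per-ORF raw signals

def _skew(g: float, c: float) -> float:
    return 0.0 if g + c == 0 else (g - c) / (g + c)


def genome_baseline_skews(record: GenomeRecord) -> tuple[float, float]:
    """(GC skew, AT skew) over the whole genome."""
    counts = np.zeros(4, dtype=np.int64)
    for _, seq in record.contigs:
        codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        counts += np.bincount(codes[codes >= 0], minlength=4)
    a, c, g, t = counts
    return _skew(g, c), _skew(a, t)


def compute_skews(
    contig_seq: str, orfs: list[OrfFeature], baseline: tuple[float, float]
) -> list[tuple[float, float]]:
    """Per-ORF (GC-skew, AT-skew) deviations from the genome baseline.

    Skew over the ORF span is (G-C)/(G+C) and (A-T)/(A+T); spans with no
    G+C (or A+T) content have skew 0.
    """
    codes = _CODE[np.frombuffer(contig_seq.encode(), dtype=np.uint8)]
    cums = np.zeros((4, len(codes) + 1), dtype=np.int64)
    for b in range(4):
        np.cumsum(codes == b, out=cums[b, 1:])
    gc0, at0 = baseline
    out = []
    for f in orfs:
        a, c, g, t = (cums[b, f.end] - cums[b, f.start] for b in range(4))
        out.append((_skew(g, c) - gc0, _skew(a, t) - at0))
    return out


def kmer_phage_score(orf_seq: str, marker_set, k: int = 12) -> float:
    """Fraction of k-mer positions in the ORF that are marker k-mers."""
    n = len(orf_seq)
    if n < k:
        logger.warning("ORF of %d bp shorter than k=%d; score 0", n, k)
        return 0.0
    marker_set = set(marker_set)
    hits = sum(1 for i in range(n - k + 1) if orf_seq[i : i + k] in marker_set)
    return hits / (n - k + 1)


def encode_markers(marker_set, k: int) -> np.ndarray:
    """Sorted integer codes (base-4) of the marker k-mers."""
    codes = []
    for km in marker_set:
        c = _CODE[np.frombuffer(km.encode(), dtype=np.uint8)]
        if len(km) != k or np.any(c < 0):
            raise ValueError(f"bad marker k-mer {km!r}")
        codes.append(int(np.dot(c.astype(np.int64), 4 ** np.arange(k - 1, -1, -1))))
    return np.sort(np.array(codes, dtype=np.int64))


def marker_position_mask(contig_seq: str, marker_codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask over k-mer start positions that match a marker."""
    codes = _CODE[np.frombuffer(contig_seq.encode(), dtype=np.uint8)].astype(np.int64)
    n = len(codes)
    if n < k:
        return np.zeros(0, dtype=bool)
    valid = codes >= 0
    codes = np.where(valid, codes, 0)
    roll = np.zeros(n - k + 1, dtype=np.int64)
    ok = np.ones(n - k + 1, dtype=bool)
    for j in range(k):
        roll = roll * 4 + codes[j : j + n - k + 1]
        ok &= valid[j : j + n - k + 1]
    idx = np.searchsorted(marker_codes, roll)
    idx[idx >= len(marker_codes)] = len(marker_codes) - 1 if len(marker_codes) else 0
    hit = ok & (len(marker_codes) > 0) & (marker_codes[idx] == roll)
    return hit


# ---------------------------------------------------------------------------
# window features

def _longest_run(strands: np.ndarray) -> int:
    best = run = 1
    for i in range(1, len(strands)):
        if strands[i] == strands[i - 1]:
            run += 1
            best = max(best, run)
        else:
            run = 1
    return best


def window_metrics(raw: pd.DataFrame, window_size: int = 30) -> pd.DataFrame:
    """Window statistics over up-to-``window_size`` ORFs centred on each ORF.

    ``raw`` must hold one row per ORF, sorted by start within each contig,
    with columns contig_id, length, strand, kmer_score_raw, gc_dev_raw,
    at_dev_raw.  Windows are truncated (never wrapped) at contig ends; the
    same-strand run fraction divides the longest run by the actual window
    length.
    """
    half = window_size // 2
    frames = []
    for _, grp in raw.groupby("contig_id", sort=False):
        n = len(grp)
        lengths = grp["length"].to_numpy(float)
        strands = grp["strand"].to_numpy()
        cums = {
            col: np.concatenate([[0.0], np.cumsum(grp[col].to_numpy(float))])
            for col in ("kmer_score_raw", "gc_dev_raw", "at_dev_raw")
        }
        med = np.empty(n)
        run = np.empty(n)
        means = {col: np.empty(n) for col in cums}
        for i in range(n):
            lo = max(0, i - half)
            hi = min(n, i + (window_size - half))
            w = hi - lo
            med[i] = np.median(lengths[lo:hi])
            run[i] = _longest_run(strands[lo:hi]) / w
            for col, cs in cums.items():
                means[col][i] = (cs[hi] - cs[lo]) / w
        out = grp.copy()
        out["median_orf_len"] = med
        out["same_strand_run"] = run
        out["phage_kmer_score"] = means["kmer_score_raw"]
        out["gc_skew_dev"] = means["gc_dev_raw"]
        out["at_skew_dev"] = means["at_dev_raw"]
        frames.append(out)
    return pd.concat(frames, ignore_index=True) if frames else raw.copy()


def orf_feature_table(
    record: GenomeRecord,
    marker_codes: np.ndarray,
    k: int = 12,
    window_size: int = 30,
    min_contig_len: int = 5000,
    min_orf_len: int = 90,
) -> pd.DataFrame:
    """The per-ORF feature table for a genome.

    Uses GenBank CDS features when present, otherwise calls ORFs from the
    sequence.  Contigs shorter than ``min_contig_len`` are skipped.
    """
    baseline = genome_baseline_skews(record)
    rows = []
    for cid, seq in record.contigs:
        if len(seq) < min_contig_len:
            continue
        orfs = record.cds_on(cid)
        if not orfs:
            orfs = call_orfs(seq, min_orf_len=min_orf_len, contig_id=cid)
        if not orfs:
            continue
        mask = marker_position_mask(seq, marker_codes, k)
        csum = np.concatenate([[0], np.cumsum(mask)])
        devs = compute_skews(seq, orfs, baseline)
        for f, (gdev, adev) in zip(orfs, devs):
            hi = max(f.start, min(f.end - k + 1, len(csum) - 1))
            npos = hi - f.start
            score = (csum[hi] - csum[f.start]) / npos if npos > 0 else 0.0
            rows.append(
                dict(
                    contig_id=cid,
                    start=f.start,
                    end=f.end,
                    strand=f.strand,
                    length=f.length,
                    annotation=f.annotation,
                    kmer_score_raw=score,
                    gc_dev_raw=gdev,
                    at_dev_raw=adev,
                )
            )
    raw = pd.DataFrame(rows)
    if raw.empty:
        return raw
    return window_metrics(raw, window_size=window_size)


# ---------------------------------------------------------------------------
# classifier

@dataclass
class ClassifierModel:
    """A fitted random-forest ORF classifier with a fixed feature schema."""

    forest: RandomForestClassifier
    features: tuple[str, ...] = FEATURE_COLUMNS
    n_trees: int = 500
    seed: int | None = None
    threshold: float = 0.5

    def _matrix(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.features if c not in table.columns]
        if missing:
            raise ValueError(f"feature table lacks columns {missing}")
        return table[list(self.features)].to_numpy(float)

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        proba = self.forest.predict_proba(self._matrix(table))
        phage_col = int(np.where(self.forest.classes_ == 1)[0][0])
        return proba[:, phage_col]

    def predict(self, table: pd.DataFrame, threshold: float | None = None) -> np.ndarray:
        th = self.threshold if threshold is None else threshold
        return self.predict_proba(table) >= th


def train_classifier(
    table: pd.DataFrame,
    labels,
    n_trees: int = 500,
    seed: int | None = None,
    threshold: float = 0.5,
    n_jobs: int = 1,
) -> ClassifierModel:
    """Fit the random-forest ORF classifier.

    ``labels`` are 1 for phage ORFs and 0 for host.  Requires both classes
    and at least 100 rows; deterministic under ``seed`` (the thread count
    does not affect predictions).
    """
    y = np.asarray(labels).astype(int)
    if len(table) < 100:
        raise ValueError(f"need >= 100 training rows, got {len(table)}")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, oob_score=True, n_jobs=n_jobs
    )
    model = ClassifierModel(forest=forest, n_trees=n_trees, seed=seed, threshold=threshold)
    forest.fit(model._matrix(table), y)
    return model


def label_orfs_by_truth(table: pd.DataFrame, truth_regions: pd.DataFrame) -> np.ndarray:
    """1 where an ORF midpoint falls inside a planted prophage, else 0."""
    labels = np.zeros(len(table), dtype=int)
    mid = ((table["start"] + table["end"]) // 2).to_numpy()
    cids = table["contig_id"].to_numpy()
    for _, r in truth_regions.iterrows():
        inside = (cids == r["contig_id"]) & (mid >= r["start"]) & (mid < r["end"])
        labels[inside] = 1
    return labels


# ---------------------------------------------------------------------------
# region assembly and refinement

def assemble_regions(
    table: pd.DataFrame,
    predictions,
    min_genes: int = 5,
    gap_tolerance: int = 2,
) -> list[ProphageRegion]:
    """Merge runs of phage-predicted ORFs into candidate regions.

    Up to ``gap_tolerance`` consecutive host-predicted ORFs are tolerated
    inside a run.  Runs with fewer than ``min_genes`` phage-predicted ORFs
    are emitted with status ``discarded`` (reason ``too_few_genes``); all
    others are left pending for verification.
    """
    pred = np.asarray(predictions, dtype=bool)
    regions: list[ProphageRegion] = []
    for cid, grp in table.groupby("contig_id", sort=False):
        idx = grp.index.to_numpy()
        p = pred[idx]
        i = 0
        n = len(idx)
        while i < n:
            if not p[i]:
                i += 1
                continue
            j = i
            last_phage = i
            gap = 0
            while j + 1 < n:
                if p[j + 1]:
                    j += 1
                    last_phage = j
                    gap = 0
                elif gap < gap_tolerance:
                    j += 1
                    gap += 1
                else:
                    break
            j = last_phage
            rows = idx[i : j + 1]
            n_phage = int(p[i : j + 1].sum())
            start = int(grp.loc[rows[0], "start"])
            end = int(grp.loc[rows, "end"].max())
            region = ProphageRegion(
                contig_id=cid, start=start, end=end, n_genes=n_phage,
                orf_rows=list(rows),
            )
            if n_phage < min_genes:
                region.status = "discarded"
                region.discard_reason = "too_few_genes"
            regions.append(region)
            i = j + 1
    return regions


def _maximal_repeat(seq: str, ls: int, rs: int, seed_len: int,
                    lwin: tuple[int, int], rwin: tuple[int, int]) -> tuple[int, int, int]:
    """Extend an exact seed match maximally within the two windows."""
    # extend left
    while (
        ls > lwin[0] and rs > rwin[0] and ls - 1 >= 0 and seq[ls - 1] == seq[rs - 1]
    ):
        ls -= 1
        rs -= 1
    length = seed_len
    # extend right
    while (
        ls + length < lwin[1]
        and rs + length < rwin[1]
        and rs + length < len(seq)
        and seq[ls + length] == seq[rs + length]
    ):
        length += 1
    return ls, rs, length


def refine_boundaries(
    region: ProphageRegion,
    contig_seq: str,
    extra_dna: int = 2000,
    min_repeat_len: int = 10,
) -> ProphageRegion:
    """Snap region boundaries to a flanking direct repeat (att site).

    Searches ``extra_dna`` bp on either side of each predicted boundary for
    the longest exact direct-repeat pair with one copy in each flank window.
    Ties prefer the pair minimising total boundary displacement.  If a pair
    >= ``min_repeat_len`` bp is found, the boundaries snap to the outer
    edges of the two copies and the att coordinates are recorded.
    """
    n = len(contig_seq)
    lwin = (max(0, region.start - extra_dna), min(n, region.start + extra_dna))
    rwin = (max(0, region.end - extra_dna), min(n, region.end + extra_dna))
    m = min_repeat_len
    if lwin[1] - lwin[0] < m or rwin[1] - rwin[0] < m:
        return region

    seeds: dict[str, list[int]] = {}
    for i in range(lwin[0], lwin[1] - m + 1):
        seeds.setdefault(contig_seq[i : i + m], []).append(i)

    candidates: set[tuple[int, int, int]] = set()
    for j in range(rwin[0], rwin[1] - m + 1):
        word = contig_seq[j : j + m]
        for i in seeds.get(word, ()):
            if i + m <= j:  # left copy strictly before, non-overlapping
                ext = _maximal_repeat(contig_seq, i, j, m, lwin, rwin)
                if ext[0] + ext[2] <= ext[1]:
                    candidates.add(ext)

    if not candidates:
        return region

    def rank(c):
        ls, rs, length = c
        displacement = abs(ls - region.start) + abs((rs + length) - region.end)
        return (-length, displacement, ls, rs)

    ls, rs, length = min(candidates, key=rank)
    region.start = ls
    region.end = rs + length
    region.att_repeat = (ls, rs, length)
    return region


# ---------------------------------------------------------------------------
# verification

DEFAULT_PHAGE_TOKENS = (
    "phage", "prophage", "integrase", "capsid", "tail", "terminase", "portal",
)


class MarkerHitProvider:
    """Hit provider backed by the synthetic marker k-mer set.

    An ORF scores a hit when at least ``min_positions`` of its k-mer
    positions are markers.  Stands in for a profile-HMM scan on synthetic
    cohorts.
    """

    def __init__(self, marker_set, k: int = 12, min_positions: int = 2):
        self.k = k
        self.min_positions = min_positions
        self.marker_codes = encode_markers(marker_set, k)

    def __call__(self, orf_seqs: list[str]) -> tuple[list[bool], list[float]]:
        hits, scores = [], []
        for seq in orf_seqs:
            mask = marker_position_mask(seq, self.marker_codes, self.k)
            count = int(mask.sum())
            score = count / max(1, len(mask))
            hits.append(count >= self.min_positions)
            scores.append(score)
        return hits, scores


class HmmHitProvider:
    """Hit provider scanning translated ORFs against profile HMMs.

    Requires ``pyhmmer`` and a pressed or plain HMM file (e.g. virus
    orthologous group profiles).  An ORF hits when any profile matches with
    E-value below the threshold.
    """

    def __init__(self, hmm_path: str, e_value: float = 1e-5):
        import pyhmmer

        self._pyhmmer = pyhmmer
        with pyhmmer.plan7.HMMFile(hmm_path) as fh:
            self.hmms = list(fh)
        self.e_value = e_value

    def __call__(self, orf_seqs: list[str]) -> tuple[list[bool], list[float]]:
        from Bio.Seq import Seq

        pyhmmer = self._pyhmmer
        alphabet = pyhmmer.easel.Alphabet.amino()
        texts = []
        for i, seq in enumerate(orf_seqs):
            prot = str(Seq(seq[: len(seq) - len(seq) % 3]).translate()).replace("*", "")
            texts.append(pyhmmer.easel.TextSequence(name=str(i).encode(), sequence=prot))
        digital = [t.digitize(alphabet) for t in texts]
        best = [np.inf] * len(orf_seqs)
        for hits in pyhmmer.hmmsearch(self.hmms, digital):
            for h in hits:
                i = int(h.name.decode())
                best[i] = min(best[i], h.evalue)
        return [b <= self.e_value for b in best], [float(b) for b in best]


def verify_region(
    region: ProphageRegion,
    table: pd.DataFrame,
    hits,
    phage_tokens=DEFAULT_PHAGE_TOKENS,
    min_phage_genes: int = 1,
) -> ProphageRegion:
    """Final keep/discard decision and verified-bp bookkeeping.

    A pending region is kept iff it retains >= 5 phage-predicted genes
    (checked at assembly) and either >= ``min_phage_genes`` of its ORFs are
    annotated with a phage token or at least one ORF has a provider hit.
    ``verified_bp_fraction`` is the fraction of region bp covered by ORFs
    with provider hits.
    """
    rows = region.orf_rows
    annots = table.loc[rows, "annotation"].fillna("").str.lower()
    tokens = tuple(t.lower() for t in phage_tokens)
    region.phage_annotated_genes = int(
        sum(any(t in a for t in tokens) for a in annots)
    )
    hits = np.asarray(hits, dtype=bool)
    hit_rows = [r for r in rows if hits[r]]
    verified_bp = 0
    for r in hit_rows:
        s = max(int(table.loc[r, "start"]), region.start)
        e = min(int(table.loc[r, "end"]), region.end)
        verified_bp += max(0, e - s)
    region.verified_bp_fraction = verified_bp / region.length if region.length else 0.0
    if region.status == "discarded":
        return region
    if region.phage_annotated_genes >= min_phage_genes or len(hit_rows) >= 1:
        region.status = "kept"
    else:
        region.status = "discarded"
        region.discard_reason = "no_phage_evidence"
    return region


# ---------------------------------------------------------------------------
# pipeline

def detect(
    record: GenomeRecord,
    model: ClassifierModel,
    config: RunConfig,
    hit_provider,
    marker_codes: np.ndarray | None = None,
    marker_set=None,
) -> list[ProphageRegion]:
    """Run the full detection pipeline on one genome.

    Returns every candidate region, kept and discarded alike, each with a
    status and (for discards) a reason.  Deterministic for a fixed model and
    configuration; invariant under contig reordering.
    """
    if marker_codes is None:
        if marker_set is None:
            raise ValueError("provide marker_codes or marker_set")
        marker_codes = encode_markers(marker_set, config.kmer_k)
    table = orf_feature_table(
        record,
        marker_codes,
        k=config.kmer_k,
        window_size=config.window_size,
        min_contig_len=config.min_contig_len,
    )
    if table.empty:
        logger.info("%s: no ORFs on retained contigs", record.accession)
        return []
    # canonical contig order so output is invariant under reordering
    table = table.sort_values(["contig_id", "start", "end"]).reset_index(drop=True)
    pred = model.predict(table)
    regions = assemble_regions(
        table, pred, min_genes=config.number, gap_tolerance=config.gap_tolerance
    )
    seqs = {cid: seq for cid, seq in record.contigs}
    for region in regions:
        refine_boundaries(
            region,
            seqs[region.contig_id],
            extra_dna=config.extra_dna,
            min_repeat_len=config.min_repeat_len,
        )
    hit_flags, _scores = hit_provider(
        [
            seqs[row.contig_id][int(row.start) : int(row.end)]
            for row in table.itertuples()
        ]
    )
    for region in regions:
        verify_region(
            region,
            table,
            hit_flags,
            phage_tokens=config.phage_tokens,
            min_phage_genes=config.phage_genes,
        )
    return regions
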