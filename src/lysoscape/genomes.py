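"""Genome and metadata input: GenBank parsing, assembly filters, date
normalisation, GTDB lineage handling, and one-genome-per-species
dereplication.

Coordinates are 0-based half-open throughout the package; GFF3 output
converts to 1-based inclusive at the boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "OrfFeature",
    "GenomeRecord",
    "read_genbank",
    "read_fasta",
    "write_genbank",
    "filter_assembly",
    "parse_isolation_date",
    "load_metadata",
    "parse_gtdb_lineage",
    "dereplicate_by_species",
]


@dataclass
class OrfFeature:
    """A protein-coding feature on a contig (0-based, half-open)."""

    contig_id: str
    start: int
    end: int
    strand: int  # +1 or -1
    annotation: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad ORF coordinates [{self.start}, {self.end})")
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1/-1, got {self.strand}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """One assembly: contigs plus CDS features."""

    accession: str
    contigs: list[tuple[str, str]]  # (contig_id, sequence)
    cds: list[OrfFeature] = field(default_factory=list)
    source: str = "unknown"  # isolate | MAG | unknown

    def __post_init__(self):
        ids = [c for c, _ in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.accession}: duplicate contig ids")
        lens = dict(self.contig_lengths.items())
        for f in self.cds:
            if f.contig_id not in lens or f.end > lens[f.contig_id]:
                raise ValueError(
                    f"{self.accession}: CDS [{f.start},{f.end}) outside contig {f.contig_id}"
                )

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {cid: len(seq) for cid, seq in self.contigs}

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    @property
    def total_bp(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)

    def contig_seq(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)

    def cds_on(self, contig_id: str) -> list[OrfFeature]:
        return sorted(
            (f for f in self.cds if f.contig_id == contig_id), key=lambda f: (f.start, f.end)
        )


def read_genbank(path) -> GenomeRecord:
    """Read a (possibly multi-record) GenBank flat file into a GenomeRecord.

    One LOCUS record per contig.  CDS features are extracted with strand and
    product text; features with coordinates outside their contig are dropped
    with a warning.  Sequences are uppercased.
    """
    path = Path(path)
    contigs: list[tuple[str, str]] = []
    cds: list[OrfFeature] = []
    accession = None
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # noqa: BLE001 - biopython raises many types
        raise ValueError(f"unparseable GenBank file {path}: {exc}") from exc
    if not records:
        raise ValueError(f"no GenBank records found in {path}")
    for rec in records:
        if accession is None:
            # a single-token DEFINITION is taken as the assembly accession
            # (the convention of our own writer); otherwise fall back to the
            # file stem, as NCBI .gbff files carry no assembly accession.
            desc = (rec.description or "").rstrip(".").strip()
            accession = desc if desc and " " not in desc else path.stem
        seq = str(rec.seq).upper()
        contigs.append((rec.id, seq))
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            start = int(feat.location.start)
            end = int(feat.location.end)
            strand = 1 if (feat.location.strand or 1) >= 0 else -1
            if not (0 <= start < end <= len(seq)):
                logger.warning(
                    "%s: dropping CDS [%d,%d) outside contig %s", path.name, start, end, rec.id
                )
                continue
            product = (feat.qualifiers.get("product") or [""])[0]
            cds.append(OrfFeature(rec.id, start, end, strand, product))
    return GenomeRecord(accession=accession, contigs=contigs, cds=cds)


def read_fasta(path) -> GenomeRecord:
    """Read a FASTA assembly (no features; ORFs can be called downstream)."""
    path = Path(path)
    contigs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeRecord(accession=path.stem, contigs=contigs, cds=[])


def write_genbank(record: GenomeRecord, path) -> None:
    """Write a GenomeRecord as a multi-record GenBank flat file."""
    out = []
    for cid, seq in record.contigs:
        rec = SeqRecord(Seq(seq), id=cid, name=cid[:16], description=record.accession)
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["accessions"] = [record.accession]
        for f in record.cds_on(cid):
            feat = SeqFeature(
                FeatureLocation(int(f.start), int(f.end), strand=int(f.strand)),
                type="CDS",
                qualifiers={"product": [f.annotation or "hypothetical protein"]},
            )
            rec.features.append(feat)
        out.append(rec)
    SeqIO.write(out, str(path), "genbank")


def filter_assembly(
    record: GenomeRecord, max_contigs: int = 100, min_contig_len: int = 5000
) -> tuple[GenomeRecord | None, list[str]]:
    """Apply the assembly quality filters.

    Assemblies with ``max_contigs`` or more contigs are excluded outright
    (only assemblies with fewer than 100 contigs are processed).  Otherwise,
    contigs shorter than ``min_contig_len`` go on the drop list: they are
    excluded from detection and from the density denominator, but the record
    itself is returned unaltered so that bp accounting remains exact.
    The length boundary is inclusive: a contig of exactly ``min_contig_len``
    bp is retained.
    """
    if record.n_contigs >= max_contigs:
        logger.info(
            "%s excluded: %d contigs >= %d", record.accession, record.n_contigs, max_contigs
        )
        return None, []
    dropped = [cid for cid, seq in record.contigs if len(seq) < min_contig_len]
    return record, dropped


_YEAR_RANGE = (1800, date.today().year + 1)
_ISO_DATE = re.compile(r"^(\d{4})[-/](\d{1,2})[-/](\d{1,2})$")
_YEAR_MONTH = re.compile(r"^(\d{4})[-/](\d{1,2})$")
_BARE_YEAR = re.compile(r"^(\d{4})$")
_DECIMAL_YEAR = re.compile(r"^(\d{4}\.\d+)$")


def _decimal_year(y: int, m: int, d: int) -> float | None:
    try:
        doy = date(y, m, d).timetuple().tm_yday
    except ValueError:
        return None
    return y + (doy - 1) / 365.0


def parse_isolation_date(raw) -> float | None:
    """Normalise an isolation-date string to a decimal year.

    Full dates map to ``year + (day_of_year - 1)/365``; year-month strings
    to the middle of the month (the 15th); bare years to mid-year
    (``year + 0.5``).  Anything unparseable, or outside [1800, next year],
    yields ``None`` — this function never raises.  It is idempotent on its
    own rendered output (decimal-year strings are accepted back).
    """
    if raw is None:
        return None
    if isinstance(raw, (int, np.integer)) and not isinstance(raw, bool):
        raw = str(raw)
    if isinstance(raw, float):
        y = raw
        return y if _YEAR_RANGE[0] <= y <= _YEAR_RANGE[1] + 1 else None
    if not isinstance(raw, str):
        return None
    s = raw.strip()
    if not s:
        return None
    m = _ISO_DATE.match(s)
    if m:
        y = _decimal_year(int(m.group(1)), int(m.group(2)), int(m.group(3)))
    else:
        m = _YEAR_MONTH.match(s)
        if m:
            y = _decimal_year(int(m.group(1)), int(m.group(2)), 15)
        else:
            m = _BARE_YEAR.match(s)
            if m:
                y = int(m.group(1)) + 0.5
            else:
                m = _DECIMAL_YEAR.match(s)
                y = float(m.group(1)) if m else None
    if y is None or not (_YEAR_RANGE[0] <= y <= _YEAR_RANGE[1] + 1):
        return None
    return y


def load_metadata(path) -> pd.DataFrame:
    """Load a tab-separated metadata table and normalise it.

    Expected columns: assembly_accession, isolation_date, country,
    gtdb_lineage, is_mag.  Duplicate rows per accession keep the first
    occurrence.  Adds ``isolation_year`` (decimal year or NaN) and
    canonicalises country labels (case/whitespace only).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "assembly_accession" not in df.columns:
        raise ValueError(f"{path}: metadata table lacks an assembly_accession column")
    df = df.drop_duplicates(subset="assembly_accession", keep="first").reset_index(drop=True)
    if "isolation_date" in df.columns:
        df["isolation_year"] = [parse_isolation_date(v) for v in df["isolation_date"]]
    if "country" in df.columns:
        df["country"] = df["country"].map(lambda s: " ".join(str(s).split()))
    if "is_mag" in df.columns:
        df["is_mag"] = df["is_mag"].map(
            lambda v: str(v).strip().lower() in ("1", "true", "yes", "mag")
        )
    return df


_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


def parse_gtdb_lineage(lineage: str) -> dict[str, str]:
    """Split a rank-prefixed GTDB lineage string into named ranks."""
    out = {r: "" for r in _RANKS}
    if not isinstance(lineage, str):
        return out
    for part in lineage.split(";"):
        part = part.strip()
        for rank, pref in zip(_RANKS, _PREFIXES):
            if part.startswith(pref):
                out[rank] = part[len(pref):].strip()
    return out


def dereplicate_by_species(summaries: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Keep exactly one genome per species, chosen uniformly at random.

    ``summaries`` must carry a ``species`` column (or a ``gtdb_lineage``
    column from which it is derived).  Rows with a missing species label are
    excluded.  Deterministic under ``seed``.
    """
    if len(summaries) == 0:
        return summaries.copy()
    df = summaries.copy()
    if "species" not in df.columns:
        if "gtdb_lineage" not in df.columns:
            raise ValueError("summaries need a species or gtdb_lineage column")
        df["species"] = df["gtdb_lineage"].map(lambda s: parse_gtdb_lineage(s)["species"])
    df = df[df["species"].astype(str).str.len() > 0]
    rng = np.random.default_rng(seed)
    # stable species order so the selection depends only on the seed
    picks = []
    for _, grp in df.groupby("species", sort=True):
        picks.append(grp.index[rng.integers(0, len(grp))])
    return df.loc[sorted(picks)].copy()
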