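"""File formats, percentage bookkeeping and run configuration.

All tabular I/O is headered, tab-separated UTF-8 with ``#`` comment
lines. FASTA is wrapped at 60 columns on write. Printed percentages use
half-up rounding to 2 decimals, the convention of the worked summary
tables this package mirrors.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "write_fasta", "write_fastq", "percent_of", "read_tsv",
           "write_tsv", "RunConfig", "load_config"]

_IUPAC = frozenset("ACGTUNRYSWKMBDHV")


def read_fasta(path) -> dict[str, str]:
    """FASTA -> ordered ``{id: sequence}``; rejects duplicates, empties
    and non-IUPAC characters, naming the offending record."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for FASTA id {rec.id!r} in {path}")
        bad = set(seq) - _IUPAC
        if bad:
            raise ValueError(
                f"non-IUPAC character(s) {sorted(bad)} in FASTA record {rec.id!r} in {path}"
            )
        records[rec.id] = seq
    return records


def write_fasta(records: dict[str, str], path) -> None:
    """Write ``{id: sequence}`` as 60-column-wrapped FASTA."""
    recs = [SeqRecord(Seq(s), id=u, description="") for u, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def write_fastq(reads, path, quality: int = 40) -> None:
    """Write simulated reads as Phred+33 FASTQ with constant quality."""
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(r.sequence)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def percent_of(part: int, whole: int, decimals: int = 2) -> float:
    """``100*part/whole`` rounded half-up to ``decimals`` places."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    if not 0 <= part <= whole:
        raise ValueError("part must lie in [0, whole]")
    q = decimal.Decimal(1).scaleb(-decimals)
    value = decimal.Decimal(100) * decimal.Decimal(part) / decimal.Decimal(whole)
    return float(value.quantize(q, rounding=decimal.ROUND_HALF_UP))


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


@dataclass
class RunConfig:
    """End-to-end pipeline parameters; defaults are the study cutoffs."""

    outdir: str = "denovotx_run"
    seed: int = 0
    # synthetic stage (desk scale)
    n_unigenes: int = 300
    library_sizes: tuple[int, int] = (30000, 30000)
    de_fraction: float = 0.1
    de_log2fc: float = 3.0
    dispersion: float = 0.0
    mean_read_depth: float = 0.0  # 0: use simulated counts directly, no read mapping
    # mapping
    k: int = 21
    max_mismatch: int = 2
    read_length: int = 75
    # significance gates
    fdr_cutoff: float = 0.001
    lfc_cutoff: float = 1.0
    alpha: float = 0.05
    correction: str = "bonferroni"
    # SSR / coding
    min_repeats: int = 5
    ssr_k_range: tuple[int, int] = (2, 6)
    min_flank_bp: int = 50
    min_product_bp: int = 150
    min_cds_bp: int = 300
    # optional external inputs (override the synthetic stage)
    unigenes_fasta: str | None = None
    counts1_tsv: str | None = None
    counts2_tsv: str | None = None
    term_map_tsv: str | None = None
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)


_TUPLE_FIELDS = {"library_sizes", "ssr_k_range"}


def load_config(path) -> RunConfig:
    """Parse a config file: YAML if available, else ``key=value`` lines."""
    text = Path(path).read_text()
    data: dict = {}
    try:
        import yaml

        loaded = yaml.safe_load(text)
        if isinstance(loaded, dict):
            data = loaded
    except Exception:
        pass
    if not data:
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, value = line.partition("=")
            data[key.strip()] = value.strip()
    cfg = RunConfig()
    valid = set(cfg.to_dict())
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, value in data.items():
        default = getattr(cfg, key)
        if key in _TUPLE_FIELDS:
            if isinstance(value, str):
                value = tuple(int(v) for v in value.replace("(", "").replace(")", "").split(","))
            else:
                value = tuple(int(v) for v in value)
        elif isinstance(default, bool):
            value = str(value).lower() in ("1", "true", "yes")
        elif isinstance(default, int):
            value = int(value)
        elif isinstance(default, float):
            value = float(value)
        setattr(cfg, key, value)
    return cfg
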