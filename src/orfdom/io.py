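"""Readers and writers: FASTA transcripts, label/Ka-Ks/annotation tables,
per-transcript profile TSVs and per-bin distribution TSVs.

All tabular output is TSV with a header line; undefined values are written
as "NA".  Labels follow the RefSeq accession convention when no explicit
table is given: NM_* is coding, NR_* is noncoding, everything else is
unlabeled (scored, but excluded from the coding/noncoding statistics).
"""

from __future__ import annotations

import logging
from os import PathLike

import numpy as np
import pandas as pd
from Bio import SeqIO

from .distributions import (
    BIN_MEDIANS,
    BinnedDistribution,
    CodingPotentialTable,
    KaKsRecord,
    OverlapResult,
    RegressionFit,
)
from .orfscan import Transcript, normalize_sequence
from .scoring import OrfProfile

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_label_table",
    "infer_labels",
    "read_kaks_table",
    "profiles_to_frame",
    "write_profiles_tsv",
    "read_profiles_tsv",
    "read_viral_annotation",
    "distribution_frame",
]

logger = logging.getLogger(__name__)


def read_fasta(path: str | PathLike) -> list[Transcript]:
    """Read a (multi-)FASTA file into normalized transcripts.

    Record ids are the token before the first whitespace in the header;
    duplicate ids are an error.
    """
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate FASTA record id {record.id!r} in {path}")
        seen.add(record.id)
        try:
            bases = normalize_sequence(str(record.seq))
        except ValueError as exc:
            raise ValueError(f"record {record.id!r}: {exc}") from exc
        transcripts.append(Transcript(id=record.id, bases=bases))
    return transcripts


def write_fasta(
    transcripts: list[Transcript], path: str | PathLike, width: int = 70
) -> None:
    """Write transcripts as wrapped FASTA."""
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.bases), width):
                fh.write(t.bases[i : i + width] + "\n")


def read_label_table(path: str | PathLike) -> dict[str, str]:
    """Read a two-column TSV (transcript_id, label) into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"label table {path} needs columns transcript_id, label")
    if df[cols[0]].duplicated().any():
        dups = df[cols[0]][df[cols[0]].duplicated()].head(5).tolist()
        raise ValueError(f"duplicate transcript ids in label table: {dups}")
    bad = set(df[cols[1]]) - {"coding", "noncoding"}
    if bad:
        raise ValueError(f"labels must be coding/noncoding, got {sorted(bad)}")
    return dict(zip(df[cols[0]], df[cols[1]]))


def infer_labels(
    transcripts: list[Transcript], table: dict[str, str] | None = None
) -> list[Transcript]:
    """Attach coding/noncoding labels from a table or the NM/NR prefix rule.

    With a table, every transcript id must be covered (an error lists the
    first 10 missing ids).  Without one, RefSeq prefixes decide: NM_* is
    coding, NR_* noncoding, anything else stays unlabeled.
    """
    if table is not None:
        missing = [t.id for t in transcripts if t.id not in table]
        if missing:
            shown = ", ".join(missing[:10])
            raise KeyError(
                f"{len(missing)} transcript id(s) missing from label table: {shown}"
            )
        labeled = [
            Transcript(id=t.id, bases=t.bases, label=table[t.id])
            for t in transcripts
        ]
    else:
        labeled = []
        for t in transcripts:
            if t.id.startswith("NM_"):
                label = "coding"
            elif t.id.startswith("NR_"):
                label = "noncoding"
            else:
                label = "unlabeled"
            labeled.append(Transcript(id=t.id, bases=t.bases, label=label))
        n_unlabeled = sum(1 for t in labeled if t.label == "unlabeled")
        if n_unlabeled:
            logger.info(
                "%d transcript(s) left unlabeled by the NM/NR prefix rule",
                n_unlabeled,
            )
    return labeled


def read_kaks_table(path: str | PathLike) -> list[KaKsRecord]:
    """Read a TSV with columns transcript_id, ka, ks."""
    df = pd.read_csv(path, sep="\t")
    for col in ("transcript_id", "ka", "ks"):
        if col not in df.columns:
            raise ValueError(f"Ka/Ks table {path} lacks required column {col!r}")
    return [
        KaKsRecord(transcript_id=str(r.transcript_id), ka=float(r.ka), ks=float(r.ks))
        for r in df.itertuples(index=False)
    ]


def profiles_to_frame(profiles: list[OrfProfile]) -> pd.DataFrame:
    """Per-transcript profile table (one row per transcript)."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "transcript_id": p.transcript_id,
                "label": p.label,
                "transcript_length": p.transcript_length,
                "n_orfs": p.n_orfs,
                "porf_aa": p.porf_length if p.porf_length else np.nan,
                "sum_secorf_aa": p.sum_secorf if p.n_orfs else np.nan,
                "dominance": p.dominance if p.dominance is not None else np.nan,
                "coverage": p.coverage if p.coverage is not None else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "label",
            "transcript_length",
            "n_orfs",
            "porf_aa",
            "sum_secorf_aa",
            "dominance",
            "coverage",
        ],
    )


def write_profiles_tsv(profiles: list[OrfProfile], path: str | PathLike) -> None:
    profiles_to_frame(profiles).to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.10g"
    )


def read_profiles_tsv(path: str | PathLike) -> list[OrfProfile]:
    """Read a profile TSV back into :class:`OrfProfile` objects.

    Individual secORF lengths are not serialized; the sum is carried in a
    single pseudo-entry, which is sufficient for every downstream statistic.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    profiles = []
    for r in df.itertuples(index=False):
        no_orf = pd.isna(r.dominance)
        sum_sec = 0 if no_orf or pd.isna(r.sum_secorf_aa) else int(r.sum_secorf_aa)
        profiles.append(
            OrfProfile(
                transcript_id=str(r.transcript_id),
                transcript_length=int(r.transcript_length),
                porf_length=0 if no_orf else int(r.porf_aa),
                secorf_lengths=[sum_sec] if sum_sec else [],
                dominance=None if no_orf else float(r.dominance),
                coverage=None if no_orf else float(r.coverage),
                label=str(r.label),
            )
        )
    return profiles


def read_viral_annotation(path: str | PathLike) -> dict[str, "ViralAnnotation"]:
    """Read vORF annotations, one :class:`ViralAnnotation` per genome.

    Two layouts are accepted: BED-like with columns genome_id, start, end,
    frame (0-based half-open nucleotide span including the stop codon), or
    lengths-only with columns genome_id, aa_length.
    """
    from .viral import ViralAnnotation

    df = pd.read_csv(path, sep="\t")
    cols = set(df.columns)
    annotations: dict[str, ViralAnnotation] = {}
    if {"genome_id", "start", "end", "frame"} <= cols:
        for gid, grp in df.groupby("genome_id", sort=False):
            spans = []
            for r in grp.itertuples(index=False):
                span_nt = int(r.end) - int(r.start)
                if span_nt < 6 or span_nt % 3 != 0:
                    raise ValueError(
                        f"span {r.start}-{r.end} of {gid} is not a whole "
                        "number of codons including a stop"
                    )
                spans.append((int(r.frame), int(r.start), span_nt // 3 - 1))
            annotations[str(gid)] = ViralAnnotation(genome_id=str(gid), spans=spans)
    elif {"genome_id", "aa_length"} <= cols:
        for gid, grp in df.groupby("genome_id", sort=False):
            annotations[str(gid)] = ViralAnnotation(
                genome_id=str(gid), lengths=[int(v) for v in grp["aa_length"]]
            )
    else:
        raise ValueError(
            f"annotation {path} needs columns (genome_id, start, end, frame) "
            "or (genome_id, aa_length)"
        )
    return annotations


def distribution_frame(
    f: BinnedDistribution,
    g: BinnedDistribution,
    potential: CodingPotentialTable | None = None,
    overlap: OverlapResult | None = None,
) -> pd.DataFrame:
    """Per-bin table of f(x), g(x) and optionally F(x) and o(x)."""
    data = {
        "bin_median": BIN_MEDIANS,
        "f": f.freqs,
        "g": g.freqs,
        "n_coding": f.counts,
        "n_noncoding": g.counts,
    }
    if potential is not None:
        data["F"] = potential.values
    if overlap is not None:
        data["o"] = overlap.o
    return pd.DataFrame(data)
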