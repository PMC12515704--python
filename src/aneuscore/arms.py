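"""Chromosome-arm model: arm definitions, per-arm read counting, and QC.

Arms are the coordinate backbone of the whole pipeline.  Each chromosome
contributes a p arm (from position 0 to the start of the first centromeric
``acen`` band) and a q arm (from the end of the last ``acen`` band to the
chromosome end); reads falling into the centromeric gap belong to no arm and
are discarded.  The acrocentric short arms 13p, 14p, 15p, 21p and 22p carry
too few LINE-1 amplicons to be informative and are excluded from scoring, as
are both arms of chromosome Y; the remaining 41 arms of chr1-22 and chrX are
the scored set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

#: Arms excluded from normalization and scoring (acrocentric short arms + Y).
EXCLUDED_ARMS = frozenset({"13p", "14p", "15p", "21p", "22p", "Yp", "Yq"})

#: Default minimum reads per sample for a profile to pass QC.
DEFAULT_MIN_READS = 90_000

#: Default minimum mapping quality for counting an aligned read.
DEFAULT_MIN_MAPQ = 30

# GRCh38 chromosome length and centromere (acen) interval per chromosome.
# (chrom, acen_start, acen_end, chrom_length)
_GRCH38_ARMS: tuple[tuple[str, int, int, int], ...] = (
    ("1", 121_700_000, 125_100_000, 248_956_422),
    ("2", 91_800_000, 96_000_000, 242_193_529),
    ("3", 87_800_000, 94_000_000, 198_295_559),
    ("4", 48_200_000, 51_800_000, 190_214_555),
    ("5", 46_100_000, 50_000_000, 181_538_259),
    ("6", 58_500_000, 62_600_000, 170_805_979),
    ("7", 58_100_000, 62_100_000, 159_345_973),
    ("8", 43_200_000, 47_200_000, 145_138_636),
    ("9", 42_200_000, 45_500_000, 138_394_717),
    ("10", 38_000_000, 41_600_000, 133_797_422),
    ("11", 51_000_000, 55_800_000, 135_086_622),
    ("12", 33_200_000, 37_800_000, 133_275_309),
    ("13", 16_500_000, 18_900_000, 114_364_328),
    ("14", 16_100_000, 18_200_000, 107_043_718),
    ("15", 17_500_000, 20_500_000, 101_991_189),
    ("16", 35_300_000, 38_400_000, 90_338_345),
    ("17", 22_700_000, 27_400_000, 83_257_441),
    ("18", 15_400_000, 21_500_000, 80_373_285),
    ("19", 24_200_000, 28_100_000, 58_617_616),
    ("20", 25_700_000, 30_400_000, 64_444_167),
    ("21", 10_900_000, 13_000_000, 46_709_983),
    ("22", 13_700_000, 17_400_000, 50_818_468),
    ("X", 58_100_000, 63_800_000, 156_040_895),
    ("Y", 10_300_000, 10_600_000, 57_227_415),
)


class CytobandError(ValueError):
    """Raised for malformed or incomplete cytoband input."""


@dataclass(frozen=True)
class ArmDefinition:
    """One chromosome arm: a half-open genomic interval plus scoring metadata.

    Parameters
    ----------
    chrom : str
        Chromosome name without the ``chr`` prefix (``"1"`` ... ``"22"``,
        ``"X"``, ``"Y"``).
    arm : str
        ``"p"`` or ``"q"``.
    start, end : int
        0-based half-open interval ``[start, end)`` in base pairs.
    included : bool
        Whether the arm enters normalization and scoring.
    weight : float
        Relative LINE-1 amplicon-abundance proxy (unitless).  Defaults to the
        arm length; the true per-arm amplicon density is assay-specific and
        configurable.
    """

    chrom: str
    arm: str
    start: int
    end: int
    included: bool = True
    weight: float = 0.0

    def __post_init__(self) -> None:
        if self.arm not in ("p", "q"):
            raise ValueError(f"arm must be 'p' or 'q', got {self.arm!r}")
        if not self.start < self.end:
            raise ValueError(f"arm {self.name}: start must be < end")
        if self.included and not self.weight > 0:
            raise ValueError(f"included arm {self.name} must have weight > 0")

    @property
    def name(self) -> str:
        """Arm label, e.g. ``"8q"``."""
        return f"{self.chrom}{self.arm}"

    @property
    def length(self) -> int:
        return self.end - self.start


def _normalize_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def _make_arms(
    table: Iterable[tuple[str, int, int, int]],
    excluded: frozenset[str] = EXCLUDED_ARMS,
) -> list[ArmDefinition]:
    arms: list[ArmDefinition] = []
    for chrom, acen_start, acen_end, length in table:
        for arm, start, end in (("p", 0, acen_start), ("q", acen_end, length)):
            name = f"{chrom}{arm}"
            arms.append(
                ArmDefinition(
                    chrom=chrom,
                    arm=arm,
                    start=start,
                    end=end,
                    included=name not in excluded,
                    weight=float(end - start),
                )
            )
    return arms


def grch38_arms() -> list[ArmDefinition]:
    """The built-in 48-arm GRCh38 model (41 arms included for scoring)."""
    return _make_arms(_GRCH38_ARMS)


def included_arms(arms: Sequence[ArmDefinition]) -> list[ArmDefinition]:
    return [a for a in arms if a.included]


def arm_names(arms: Sequence[ArmDefinition], only_included: bool = False) -> list[str]:
    return [a.name for a in arms if a.included or not only_included]


def load_cytobands(source: str | Path | pd.DataFrame) -> list[ArmDefinition]:
    """Build arm definitions from a UCSC-style cytoband table.

    The table must have columns (chrom, start, end, band name, Giemsa stain),
    tab-separated when read from a file.  The p arm spans from 0 to the start
    of the first ``acen`` band, the q arm from the end of the last ``acen``
    band to the chromosome end.  Default exclusions (acrocentric short arms
    and Y) and length-proportional weights are applied.

    Raises
    ------
    CytobandError
        If a chromosome has no ``acen`` band, or a row is malformed (the
        error names the chromosome / 1-based line number).
    """
    if isinstance(source, pd.DataFrame):
        df = source.iloc[:, :5].copy()
        df.columns = ["chrom", "start", "end", "band", "stain"]
    else:
        rows = []
        with open(source) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 5:
                    raise CytobandError(
                        f"malformed cytoband row at line {lineno}: "
                        f"expected 5 tab-separated fields, got {len(parts)}"
                    )
                try:
                    rows.append(
                        (parts[0], int(parts[1]), int(parts[2]), parts[3], parts[4])
                    )
                except ValueError as exc:
                    raise CytobandError(
                        f"malformed cytoband row at line {lineno}: {exc}"
                    ) from exc
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "band", "stain"])

    df["chrom"] = df["chrom"].map(_normalize_chrom)
    table = []
    for chrom, grp in df.groupby("chrom", sort=False):
        acen = grp[grp["stain"] == "acen"]
        if acen.empty:
            raise CytobandError(f"chromosome {chrom} has no acen band")
        table.append(
            (chrom, int(acen["start"].min()), int(acen["end"].max()), int(grp["end"].max()))
        )
    order = {c: i for i, (c, *_ ) in enumerate(_GRCH38_ARMS)}
    table.sort(key=lambda row: order.get(row[0], len(order)))
    return _make_arms(tuple(table))


def set_weights(
    arms: Sequence[ArmDefinition], weights: Mapping[str, float]
) -> list[ArmDefinition]:
    """Return a copy of ``arms`` with per-arm weights replaced."""
    return [replace(a, weight=float(weights.get(a.name, a.weight))) for a in arms]


@dataclass
class ArmCountProfile:
    """One sample's raw read counts over arms plus QC metadata.

    ``counts`` may carry excluded arms for diagnostics; ``total_reads`` is
    always the sum over *included* arms only, and ``qc_pass`` is True iff
    that total reaches ``min_reads`` (default 90,000).
    """

    sample_id: str
    counts: dict[str, int]
    total_reads: int
    qc_pass: bool
    timepoint: str = "baseline"
    min_reads: int = DEFAULT_MIN_READS

    @classmethod
    def from_counts(
        cls,
        sample_id: str,
        counts: Mapping[str, int],
        arms: Sequence[ArmDefinition],
        timepoint: str = "baseline",
        min_reads: int = DEFAULT_MIN_READS,
    ) -> "ArmCountProfile":
        counts = {k: int(v) for k, v in counts.items()}
        if any(v < 0 for v in counts.values()):
            raise ValueError("read counts must be nonnegative")
        incl = {a.name for a in included_arms(arms)}
        total = sum(v for k, v in counts.items() if k in incl)
        return cls(
            sample_id=sample_id,
            counts=counts,
            total_reads=total,
            qc_pass=total >= min_reads,
            timepoint=timepoint,
            min_reads=min_reads,
        )


def qc_check(profile: ArmCountProfile, min_reads: int = DEFAULT_MIN_READS) -> bool:
    """Re-evaluate QC (total included-arm reads >= ``min_reads``) in place."""
    profile.min_reads = min_reads
    profile.qc_pass = profile.total_reads >= min_reads
    return profile.qc_pass


def _iter_sam(path: str | Path) -> Iterator[tuple[str, int, int]]:
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            yield read.reference_name, read.reference_start, read.mapping_quality


def count_reads_per_arm(
    alignments: str | Path | Iterable[tuple[str, int, int]],
    arms: Sequence[ArmDefinition],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    sample_id: str = "sample",
    timepoint: str = "baseline",
    min_reads: int = DEFAULT_MIN_READS,
) -> ArmCountProfile:
    """Count aligned reads per arm by leftmost position (half-open intervals).

    ``alignments`` is a SAM/BAM path or an iterable of
    ``(chrom, leftmost_pos, mapq)`` tuples.  Reads below ``min_mapq``, on
    contigs absent from the arm model, or inside the centromeric gap are
    discarded.  Excluded arms are counted (for diagnostics) but do not enter
    ``total_reads``.  An input with no passing reads yields an all-zero
    profile with ``qc_pass=False``.
    """
    if isinstance(alignments, (str, Path)):
        alignments = _iter_sam(alignments)

    by_chrom: dict[str, list[ArmDefinition]] = {}
    for a in arms:
        by_chrom.setdefault(a.chrom, []).append(a)

    counts = {a.name: 0 for a in arms}
    for chrom, pos, mapq in alignments:
        if mapq < min_mapq:
            continue
        chrom_arms = by_chrom.get(_normalize_chrom(chrom))
        if chrom_arms is None:
            continue
        for a in chrom_arms:
            if a.start <= pos < a.end:
                counts[a.name] += 1
                break
    return ArmCountProfile.from_counts(
        sample_id, counts, arms, timepoint=timepoint, min_reads=min_reads
    )


# ---------------------------------------------------------------------------
# File formats


def arms_to_bed(arms: Sequence[ArmDefinition], path: str | Path) -> None:
    """Write arms as BED4 (0-based half-open; name ``chrom_arm``; score = included)."""
    with open(path, "w") as fh:
        for a in arms:
            fh.write(
                f"chr{a.chrom}\t{a.start}\t{a.end}\t{a.chrom}_{a.arm}\t{int(a.included)}\n"
            )


def arms_from_bed(path: str | Path) -> list[ArmDefinition]:
    arms = []
    with open(path) as fh:
        for line in fh:
            chrom, start, end, name, score = line.rstrip("\n").split("\t")[:5]
            c, arm = name.rsplit("_", 1)
            arms.append(
                ArmDefinition(
                    chrom=_normalize_chrom(c),
                    arm=arm,
                    start=int(start),
                    end=int(end),
                    included=bool(int(score)),
                    weight=float(int(end) - int(start)),
                )
            )
    return arms


def profiles_to_table(
    profiles: Sequence[ArmCountProfile], arms: Sequence[ArmDefinition]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count matrix (rows=arms, columns=samples) and a sample metadata sheet."""
    names = arm_names(arms)
    mat = pd.DataFrame(
        {p.sample_id: [p.counts.get(n, 0) for n in names] for p in profiles},
        index=pd.Index(names, name="arm"),
    )
    meta = pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in profiles],
            "timepoint": [p.timepoint for p in profiles],
            "total_reads": [p.total_reads for p in profiles],
            "qc_pass": [p.qc_pass for p in profiles],
        }
    )
    return mat, meta


def write_count_table(
    profiles: Sequence[ArmCountProfile],
    arms: Sequence[ArmDefinition],
    counts_path: str | Path,
    meta_path: str | Path | None = None,
) -> None:
    mat, meta = profiles_to_table(profiles, arms)
    mat.to_csv(counts_path, sep="\t")
    if meta_path is not None:
        meta.to_csv(meta_path, sep="\t", index=False)


def read_count_table(
    counts_path: str | Path,
    arms: Sequence[ArmDefinition],
    meta_path: str | Path | None = None,
    min_reads: int = DEFAULT_MIN_READS,
) -> list[ArmCountProfile]:
    """Load a TSV count matrix (rows=arms, columns=samples) into profiles."""
    mat = pd.read_csv(counts_path, sep="\t", index_col=0)
    timepoints: dict[str, str] = {}
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t")
        timepoints = dict(zip(meta["sample_id"].astype(str), meta["timepoint"]))
    return [
        ArmCountProfile.from_counts(
            str(col),
            mat[col].to_dict(),
            arms,
            timepoint=timepoints.get(str(col), "baseline"),
            min_reads=min_reads,
        )
        for col in mat.columns
    ]
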