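"""Readers/writers for the tab-delimited tables the pipeline consumes and emits.

Supported inputs are Axiom-style exports: a ``calls`` matrix (markers x
samples, integer genotype codes), a ``summary`` matrix with two rows per
SNP (``<marker>-A`` / ``<marker>-B`` allele intensities), per-sample
"Log Ratio"/"Strength" exports, and a marker annotation table. Outputs
are per-marker track TSVs, BED / TSV region files and a run-parameter log.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: genotype codes (vendor dialect {0,1,2,-1}); configurable via ``code_map``
GT_AA = 0
GT_AB = 1
GT_BB = 2
GT_NOCALL = -1

DEFAULT_CODE_MAP = {0: GT_AA, 1: GT_AB, 2: GT_BB, -1: GT_NOCALL}

_CHROM_ORDER = {str(i): i for i in range(1, 23)}
_CHROM_ORDER.update({"X": 23, "Y": 24, "MT": 25, "M": 25})


def normalize_chromosome(label: str) -> str:
    """Strip a leading ``chr`` prefix and canonicalize the label."""
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label


def chromosome_sort_key(label: str) -> tuple[int, str]:
    return (_CHROM_ORDER.get(label, 99), label)


@dataclass
class MarkerAnnotation:
    """Ordered genomic coordinate system for every per-marker track.

    Markers are strictly sorted by (chromosome, position); ``marker_id``
    is unique. ``probe_class`` is ``"SNP"`` or ``"CN"``; CN probes carry
    no genotype.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray
    probe_class: np.ndarray

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chromosome = np.asarray(
            [normalize_chromosome(c) for c in self.chromosome], dtype=object
        )
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.allele_a = np.asarray(self.allele_a, dtype=object)
        self.allele_b = np.asarray(self.allele_b, dtype=object)
        self.probe_class = np.asarray(self.probe_class, dtype=object)
        n = len(self.marker_id)
        for name in ("chromosome", "position_bp", "allele_a", "allele_b", "probe_class"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"annotation column {name!r} has wrong length")
        if np.any((self.position_bp < 1)):
            raise ValueError("positions must be 1-based (>= 1)")
        order = sorted(
            range(n),
            key=lambda i: chromosome_sort_key(self.chromosome[i]) + (int(self.position_bp[i]),),
        )
        if order != list(range(n)):
            idx = np.asarray(order)
            for name in (
                "marker_id",
                "chromosome",
                "position_bp",
                "allele_a",
                "allele_b",
                "probe_class",
            ):
                setattr(self, name, getattr(self, name)[idx])
        ids, counts = np.unique(self.marker_id.astype(str), return_counts=True)
        if np.any(counts > 1):
            raise ValueError(f"duplicate marker ids: {ids[counts > 1][:5].tolist()}")
        self._index = {mid: i for i, mid in enumerate(self.marker_id)}

    def __len__(self) -> int:
        return len(self.marker_id)

    @property
    def is_snp(self) -> np.ndarray:
        return self.probe_class == "SNP"

    @property
    def is_autosomal(self) -> np.ndarray:
        return np.isin(self.chromosome, [str(i) for i in range(1, 23)])

    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for c in self.chromosome:
            if not seen or seen[-1] != c:
                seen.append(c)
        return seen

    def chromosome_slice(self, chrom: str) -> slice:
        chrom = normalize_chromosome(chrom)
        idx = np.flatnonzero(self.chromosome == chrom)
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} not in annotation")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def index_of(self, marker_id: str) -> int:
        return self._index[marker_id]


@dataclass
class SampleData:
    """Per-sample allele intensities and genotype calls aligned to an annotation.

    ``h_a``/``h_b`` are nonnegative linear-scale intensities (NaN where the
    marker is missing for this sample); ``genotype`` uses the integer codes
    ``GT_AA``/``GT_AB``/``GT_BB``/``GT_NOCALL``.
    """

    sample_id: str
    h_a: np.ndarray
    h_b: np.ndarray
    genotype: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.h_a = np.asarray(self.h_a, dtype=float)
        self.h_b = np.asarray(self.h_b, dtype=float)
        self.genotype = np.asarray(self.genotype, dtype=np.int8)
        if not (len(self.h_a) == len(self.h_b) == len(self.genotype)):
            raise ValueError("intensity/genotype vectors must have equal length")
        with np.errstate(invalid="ignore"):
            if np.any(self.h_a < 0) or np.any(self.h_b < 0):
                raise ValueError("allele intensities must be nonnegative")

    def __len__(self) -> int:
        return len(self.h_a)

    @property
    def total_intensity(self) -> np.ndarray:
        return self.h_a + self.h_b

    @property
    def raw_af(self) -> np.ndarray:
        """Relative intensity of allele A, h_A/(h_A+h_B); NaN where undefined."""
        total = self.h_a + self.h_b
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(total > 0, self.h_a / total, np.nan)
        return af


def convert_log_ratio_strength(strength, log_ratio):
    """Invert the (Strength, Log Ratio) encoding into allele intensities.

    ``strength`` is the arithmetic mean of the log2 allele intensities and
    ``log_ratio`` the log2 ratio of allele A to allele B, so
    ``h_A = 2**(S + 0.5 L)`` and ``h_B = 2**(S - 0.5 L)``.
    """
    s = np.asarray(strength, dtype=float)
    l = np.asarray(log_ratio, dtype=float)
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(l))):
        raise ValueError("Strength / Log Ratio values must be finite")
    h_a = np.exp2(s + 0.5 * l)
    h_b = np.exp2(s - 0.5 * l)
    if s.ndim == 0:
        return float(h_a), float(h_b)
    return h_a, h_b


def read_annotation(path: str | os.PathLike) -> MarkerAnnotation:
    """Read a marker annotation TSV.

    Expected columns: marker_id, chromosome, position, allele_A, allele_B,
    probe_class (case-insensitive; ``position_bp`` accepted for position).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = {c.lower(): c for c in df.columns}

    def col(*names: str) -> pd.Series:
        for name in names:
            if name in cols:
                return df[cols[name]]
        raise ValueError(f"annotation file {path} lacks a column named one of {names}")

    return MarkerAnnotation(
        marker_id=col("marker_id", "probeset_id", "id").to_numpy(),
        chromosome=col("chromosome", "chrom", "chr").to_numpy(),
        position_bp=col("position", "position_bp", "pos").astype(np.int64).to_numpy(),
        allele_a=col("allele_a").to_numpy(),
        allele_b=col("allele_b").to_numpy(),
        probe_class=col("probe_class", "class").str.upper().to_numpy(),
    )


def read_genotype_intensity_tables(
    calls_path: str | os.PathLike,
    summary_path: str | os.PathLike,
    annotation: MarkerAnnotation,
    code_map: dict[int, int] | None = None,
) -> list[SampleData]:
    """Parse a calls matrix plus an allele-intensity summary matrix.

    The calls table is markers x samples with integer genotype codes; the
    summary table carries two rows per SNP marker, ``<id>-A`` and ``<id>-B``.
    Sample columns must match between the two files. Markers absent from
    either file become missing (NaN / NoCall) for every sample; a marker in
    the files but not in the annotation is a hard error.
    """
    code_map = dict(DEFAULT_CODE_MAP if code_map is None else code_map)
    calls = pd.read_csv(calls_path, sep="\t", index_col=0, comment="#")
    summary = pd.read_csv(summary_path, sep="\t", index_col=0, comment="#")
    if list(calls.columns) != list(summary.columns):
        raise ValueError(
            "sample columns differ between calls and summary files: "
            f"{list(calls.columns)} vs {list(summary.columns)}"
        )

    known = set(annotation.marker_id)
    for mid in calls.index:
        if mid not in known:
            raise ValueError(f"marker {mid!r} in calls table is absent from the annotation")
    base_ids = set()
    for rid in summary.index:
        if not (rid.endswith("-A") or rid.endswith("-B")):
            raise ValueError(f"summary row {rid!r} lacks an -A/-B allele suffix")
        base = rid[:-2]
        if base not in known:
            raise ValueError(f"marker {base!r} in summary table is absent from the annotation")
        base_ids.add(base)
    for base in sorted(base_ids):
        for suffix in ("-A", "-B"):
            if base + suffix not in summary.index:
                raise ValueError(f"summary table is missing row {base + suffix!r} for marker {base!r}")

    n_markers = len(annotation)
    n_samples = calls.shape[1]
    h_a = np.full((n_markers, n_samples), np.nan)
    h_b = np.full((n_markers, n_samples), np.nan)
    geno = np.full((n_markers, n_samples), GT_NOCALL, dtype=np.int8)

    calls_values = calls.to_numpy()
    for row, mid in enumerate(calls.index):
        i = annotation.index_of(mid)
        for j in range(n_samples):
            code = int(calls_values[row, j])
            if code not in code_map:
                raise ValueError(f"unknown genotype code {code} at marker {mid!r}")
            geno[i, j] = code_map[code]
    for base in base_ids:
        i = annotation.index_of(base)
        h_a[i, :] = summary.loc[base + "-A"].to_numpy(dtype=float)
        h_b[i, :] = summary.loc[base + "-B"].to_numpy(dtype=float)

    return [
        SampleData(sample_id=str(name), h_a=h_a[:, j], h_b=h_b[:, j], genotype=geno[:, j])
        for j, name in enumerate(calls.columns)
    ]


def read_log_ratio_strength(
    path: str | os.PathLike,
    annotation: MarkerAnnotation,
    sample_id: str | None = None,
) -> SampleData:
    """Read a per-sample "Log Ratio"/"Strength" export and convert to intensities.

    Genotype calls are not part of this export; all markers are NoCall.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.strip().lower().replace(" ", "_"): c for c in df.columns}
    try:
        id_col = cols.get("marker_id") or cols.get("probeset_id") or cols["id"]
        lr_col = cols.get("log_ratio") or cols["logratio"]
        st_col = cols["strength"]
    except KeyError as exc:
        raise ValueError(f"{path}: expected marker id, 'Log Ratio' and 'Strength' columns") from exc

    n = len(annotation)
    h_a = np.full(n, np.nan)
    h_b = np.full(n, np.nan)
    geno = np.full(n, GT_NOCALL, dtype=np.int8)
    known = set(annotation.marker_id)
    for mid, lr, st in zip(df[id_col], df[lr_col], df[st_col]):
        if mid not in known:
            raise ValueError(f"marker {mid!r} in {path} is absent from the annotation")
        i = annotation.index_of(mid)
        h_a[i], h_b[i] = convert_log_ratio_strength(float(st), float(lr))
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return SampleData(sample_id=sample_id, h_a=h_a, h_b=h_b, genotype=geno)


# ---------------------------------------------------------------------------
# output


def _region_sort_key(region):
    return chromosome_sort_key(normalize_chromosome(region.chromosome)) + (
        int(region.start_bp),
        int(region.end_bp),
    )


def write_regions_bed(regions, path: str | os.PathLike) -> None:
    """Write regions as BED (0-based half-open, name=type, score=-log10 p, capped)."""
    regions = sorted(regions, key=_region_sort_key)
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\n")
        for r in regions:
            p = getattr(r, "min_p", None)
            if p is None or not np.isfinite(p) or p <= 0:
                score = 1000.0
            else:
                score = min(1000.0, -np.log10(p))
            fh.write(
                f"{normalize_chromosome(r.chromosome)}\t{int(r.start_bp) - 1}\t{int(r.end_bp)}\t"
                f"{r.kind}\t{score:.4g}\n"
            )


def write_regions_tsv(regions, path: str | os.PathLike) -> None:
    """Write regions as TSV with 1-based inclusive coordinates."""
    regions = sorted(regions, key=_region_sort_key)
    with open(path, "w") as fh:
        fh.write("chromosome\tstart\tend\ttype\tn_markers\tmin_p\tmean_wap\n")
        for r in regions:
            min_p = getattr(r, "min_p", np.nan)
            mean_wap = getattr(r, "mean_wap", np.nan)
            fh.write(
                f"{normalize_chromosome(r.chromosome)}\t{int(r.start_bp)}\t{int(r.end_bp)}\t"
                f"{r.kind}\t{int(r.n_markers)}\t{_fmt(min_p)}\t{_fmt(mean_wap)}\n"
            )


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    return f"{x:.6g}"


def write_tracks_tsv(annotation: MarkerAnnotation, tracks: dict[str, np.ndarray], path) -> None:
    """Write aligned per-marker tracks (dict of name -> vector) as a TSV."""
    data = {
        "marker_id": annotation.marker_id,
        "chromosome": annotation.chromosome,
        "position": annotation.position_bp,
    }
    for name, values in tracks.items():
        values = np.asarray(values)
        if len(values) != len(annotation):
            raise ValueError(f"track {name!r} has length {len(values)} != {len(annotation)}")
        data[name] = values
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def write_run_params(params: dict, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for key in sorted(params):
            fh.write(f"{key}\t{params[key]}\n")


def export_results(
    annotation: MarkerAnnotation,
    tracks: dict[str, np.ndarray],
    regions,
    out_dir: str | os.PathLike,
    params: dict | None = None,
    prefix: str = "sample",
) -> dict[str, str]:
    """Export per-marker tracks, regions (BED + TSV) and a run-parameter log."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "tracks": os.path.join(out_dir, f"{prefix}.tracks.tsv"),
        "bed": os.path.join(out_dir, f"{prefix}.regions.bed"),
        "regions": os.path.join(out_dir, f"{prefix}.regions.tsv"),
        "params": os.path.join(out_dir, f"{prefix}.run_params.txt"),
    }
    write_tracks_tsv(annotation, tracks, paths["tracks"])
    write_regions_bed(regions, paths["bed"])
    write_regions_tsv(regions, paths["regions"])
    write_run_params(params or {}, paths["params"])
    return paths
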