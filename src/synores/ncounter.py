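"""Hybridisation-count (nCounter) ingestion and cross-platform calibration.

One RCC file describes one lane: sections delimited by ``<Tag>``/``</Tag>``
markers with comma-separated rows; the ``Code_Summary`` section carries
``CodeClass,Name,Accession,Count`` rows for Endogenous, Housekeeping,
Positive and Negative probes.

Normalisation follows platform convention: a positive-control factor per
lane (overall positive geometric mean over the lane's positive geometric
mean), then a housekeeping geometric-mean factor computed on the stable
housekeeping probes. Calibration to the sequencing scale fits, per gene,
``VST ~ b0 + b1 * log(normalised count + offset)`` on matched samples; the
stored coefficients then convert any future run to pseudo-RNA-Seq that
finalised models accept directly.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import VSTMatrix

__all__ = [
    "NCounterRun",
    "CalibrationMap",
    "DEFAULT_HK_EXCLUDE",
    "read_rcc",
    "write_rcc",
    "normalize_ncounter",
    "hk_stability",
    "fit_calibration",
    "to_pseudo_rnaseq",
    "select_panel_genes",
    "batch_adjust",
    "log_counts",
]

PROBE_CLASSES = ("Endogenous", "Housekeeping", "Positive", "Negative")

#: Housekeeping probes excluded from normalisation after stability
#: screening on the panel test runs.
DEFAULT_HK_EXCLUDE = ("ISY1", "STK11IP", "TFRC")

#: Offset added before taking the natural log of normalised counts.
LOG_OFFSET = 1.0


@dataclass
class NCounterRun:
    """Parsed multi-lane run: probes x lanes counts plus probe metadata."""

    counts: pd.DataFrame  # probes x lanes, int
    probe_info: pd.DataFrame  # index probe name; columns CodeClass, Accession
    lane_attrs: pd.DataFrame  # index lane id
    has_negatives: bool = True

    def probes_of_class(self, cls: str) -> list[str]:
        return list(self.probe_info.index[self.probe_info["CodeClass"] == cls])


@dataclass
class CalibrationMap:
    """Per-gene linear map between platforms.

    ``table`` holds intercept ``b0``, slope ``b1``, Pearson ``r`` and the
    number of matched samples per gene; the fit scale is
    VST ~ b0 + b1 * ln(normalised count + offset).
    """

    table: pd.DataFrame  # index gene; columns b0, b1, r, n
    log_offset: float = LOG_OFFSET

    def __post_init__(self):
        if (self.table["n"] < 3).any():
            raise ValueError("calibration entries need n >= 3 matched samples")
        if not np.isfinite(self.table[["b0", "b1"]].to_numpy()).all():
            raise ValueError("calibration coefficients must be finite")


def log_counts(values, offset: float = LOG_OFFSET):
    """Natural-log transform of (normalised) counts with a zero offset."""
    return np.log(np.asarray(values, dtype=float) + offset)


# ---------------------------------------------------------------- RCC files


def read_rcc(paths) -> NCounterRun:
    """Read one or more RCC lane files into a single run."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    lane_counts = {}
    probe_info = None
    lane_rows = []
    has_neg = True
    for path in paths:
        sections = _parse_sections(Path(path))
        if "Code_Summary" not in sections:
            raise ValueError(f"{path}: missing Code_Summary section")
        lane_id, attrs = _lane_attrs(sections, Path(path).stem)
        rows = sections["Code_Summary"]
        header = rows[0]
        if [h.strip() for h in header[:4]] != ["CodeClass", "Name", "Accession", "Count"]:
            raise ValueError(f"{path}: unexpected Code_Summary header {header}")
        info = {}
        counts = {}
        for ln, row in enumerate(rows[1:], start=2):
            if len(row) < 4 or not row[1]:
                continue
            cls, name, acc, cnt = row[0], row[1], row[2], row[3]
            if name in counts:
                raise ValueError(f"{path}: duplicate probe {name!r} within lane")
            try:
                value = int(cnt)
            except ValueError:
                raise ValueError(
                    f"{path}: non-integer count {cnt!r} for probe {name!r} "
                    f"(Code_Summary line {ln})"
                ) from None
            if value < 0:
                raise ValueError(f"{path}: negative count for probe {name!r}")
            counts[name] = value
            info[name] = (cls, acc)
        this_info = pd.DataFrame.from_dict(
            info, orient="index", columns=["CodeClass", "Accession"]
        )
        if probe_info is None:
            probe_info = this_info
        elif not probe_info.index.equals(this_info.index):
            raise ValueError(f"{path}: probe content differs from earlier lanes")
        lane_counts[lane_id] = counts
        lane_rows.append(attrs)
    counts_df = pd.DataFrame(lane_counts).loc[probe_info.index]
    if "Negative" not in set(probe_info["CodeClass"]):
        warnings.warn("run contains no Negative probes; background options disabled")
        has_neg = False
    if not {"Housekeeping", "Positive"} <= set(probe_info["CodeClass"]):
        raise ValueError("run needs Housekeeping and Positive probes for normalisation")
    lane_attrs = pd.DataFrame(lane_rows).set_index("ID")
    return NCounterRun(counts_df.astype(np.int64), probe_info, lane_attrs, has_neg)


def _parse_sections(path: Path) -> dict[str, list[list[str]]]:
    sections: dict[str, list[list[str]]] = {}
    current = None
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("</") and line.endswith(">"):
            current = None
        elif line.startswith("<") and line.endswith(">"):
            current = line[1:-1]
            sections[current] = []
        elif current is not None:
            sections[current].append(line.split(","))
    return sections


def _lane_attrs(sections, fallback_id):
    attrs = {"ID": fallback_id}
    for row in sections.get("Lane_Attributes", []):
        if len(row) >= 2:
            attrs[row[0]] = row[1]
    return attrs["ID"], attrs


def write_rcc(run: NCounterRun, directory, prefix: str = "lane") -> list[Path]:
    """Write one RCC file per lane; inverse of :func:`read_rcc`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for lane in run.counts.columns:
        lines = ["<Header>", "FileVersion,1.7", "SoftwareVersion,synores", "</Header>"]
        lines += ["<Lane_Attributes>", f"ID,{lane}"]
        for key, val in run.lane_attrs.loc[lane].items():
            if key != "ID" and pd.notna(val):
                lines.append(f"{key},{val}")
        lines += ["</Lane_Attributes>", "<Code_Summary>", "CodeClass,Name,Accession,Count"]
        for probe in run.counts.index:
            cls = run.probe_info.loc[probe, "CodeClass"]
            acc = run.probe_info.loc[probe, "Accession"]
            lines.append(f"{cls},{probe},{acc},{int(run.counts.loc[probe, lane])}")
        lines += ["</Code_Summary>", ""]
        path = directory / f"{prefix}_{lane}.RCC"
        path.write_text("\n".join(lines))
        paths.append(path)
    return paths


# ------------------------------------------------------------- normalisation


def _geomean(x: np.ndarray) -> np.ndarray:
    return np.exp(np.log(np.maximum(x, 0.5)).mean(axis=0))


def normalize_ncounter(
    run: NCounterRun,
    exclude_hk=DEFAULT_HK_EXCLUDE,
    background: str | None = None,
) -> pd.DataFrame:
    """Positive-control then housekeeping normalisation of endogenous probes.

    Each lane is scaled by (geometric mean of the lane positive-control
    geomeans across lanes) / (this lane's positive geomean), then by the
    analogous housekeeping factor computed on the non-excluded
    housekeeping probes. ``background='negative_2sd'`` floors values at
    mean + 2 sd of the lane's negative probes (off by default).
    """
    pos = run.counts.loc[run.probes_of_class("Positive")].to_numpy(dtype=float)
    hk_names = [g for g in run.probes_of_class("Housekeeping") if g not in set(exclude_hk)]
    if not hk_names:
        raise ValueError("no housekeeping probes left after exclusions")
    pos_gm = _geomean(pos)
    if (pos_gm <= 0).any():
        raise ValueError("zero positive-control geometric mean in a lane")
    pos_factor = np.exp(np.log(pos_gm).mean()) / pos_gm
    hk = run.counts.loc[hk_names].to_numpy(dtype=float) * pos_factor[None, :]
    hk_gm = _geomean(hk)
    if (hk_gm <= 0).any():
        raise ValueError("zero housekeeping geometric mean in a lane")
    hk_factor = np.exp(np.log(hk_gm).mean()) / hk_gm
    endo = run.counts.loc[run.probes_of_class("Endogenous")]
    out = endo.to_numpy(dtype=float) * (pos_factor * hk_factor)[None, :]
    if background == "negative_2sd":
        if not run.has_negatives:
            raise ValueError("run has no Negative probes for background flooring")
        neg = run.counts.loc[run.probes_of_class("Negative")].to_numpy(dtype=float)
        neg = neg * (pos_factor * hk_factor)[None, :]
        floor = neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)
        out = np.maximum(out, floor[None, :])
    elif background is not None:
        raise ValueError(f"unknown background mode {background!r}")
    return pd.DataFrame(out, index=endo.index, columns=endo.columns)


def hk_stability(run: NCounterRun, cv_threshold: float = 0.2) -> pd.DataFrame:
    """Rank housekeeping probes by expression stability.

    Counts are positive-control normalised first so lane throughput does
    not masquerade as instability. Stability is the geometric coefficient
    of variation computed from the log normalised counts,
    ``sqrt(exp(sd_log^2) - 1)`` (count-scale CV semantics, robust to the
    absolute expression level); probes above ``cv_threshold`` are flagged
    for exclusion.
    """
    if run.counts.shape[1] < 2:
        raise ValueError("stability screening needs >= 2 lanes")
    pos = run.counts.loc[run.probes_of_class("Positive")].to_numpy(dtype=float)
    pos_gm = _geomean(pos)
    factor = np.exp(np.log(pos_gm).mean()) / pos_gm
    hk = run.counts.loc[run.probes_of_class("Housekeeping")].to_numpy(dtype=float)
    logs = log_counts(hk * factor[None, :])
    cv = np.sqrt(np.exp(logs.var(axis=1, ddof=1)) - 1.0)
    out = pd.DataFrame(
        {"cv": cv, "flagged": cv > cv_threshold},
        index=run.probes_of_class("Housekeeping"),
    ).sort_values("cv")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# --------------------------------------------------------------- calibration


def fit_calibration(
    vst: VSTMatrix | pd.DataFrame,
    ncounter_norm: pd.DataFrame,
    min_samples: int = 3,
    log_offset: float = LOG_OFFSET,
) -> CalibrationMap:
    """Fit per-gene linear maps VST ~ b0 + b1 * ln(normalised count + offset).

    Uses samples present on both platforms; genes with fewer than
    ``min_samples`` matches or zero variance on either platform are
    skipped with a log entry (warning).
    """
    vst_df = vst.values if isinstance(vst, VSTMatrix) else vst
    genes = [g for g in vst_df.index if g in ncounter_norm.index]
    samples = [s for s in vst_df.columns if s in ncounter_norm.columns]
    if len(samples) < min_samples:
        raise ValueError(
            f"only {len(samples)} matched samples; need >= {min_samples}"
        )
    rows = {}
    skipped = []
    x_all = log_counts(ncounter_norm.loc[genes, samples].to_numpy(), log_offset)
    y_all = vst_df.loc[genes, samples].to_numpy(dtype=float)
    for i, g in enumerate(genes):
        x, yv = x_all[i], y_all[i]
        if x.std() == 0 or yv.std() == 0:
            skipped.append(g)
            continue
        b1, b0 = np.polyfit(x, yv, 1)
        r = float(np.corrcoef(x, yv)[0, 1])
        rows[g] = (float(b0), float(b1), r, len(samples))
    if skipped:
        warnings.warn(f"calibration skipped {len(skipped)} zero-variance gene(s)")
    if not rows:
        raise ValueError("no gene could be calibrated")
    table = pd.DataFrame.from_dict(rows, orient="index", columns=["b0", "b1", "r", "n"])
    return CalibrationMap(table, log_offset)


def to_pseudo_rnaseq(
    ncounter_norm: pd.DataFrame,
    cmap: CalibrationMap,
    genes=None,
) -> pd.DataFrame:
    """Convert normalised hybridisation counts to the VST scale.

    ``pseudo_gs = b0_g + b1_g * ln(normalised count + offset)``; the result
    can be fed to finalised models as if it were RNA-Seq VST data.
    """
    genes = list(genes) if genes is not None else list(ncounter_norm.index)
    missing = [g for g in genes if g not in cmap.table.index]
    if missing:
        raise KeyError(f"gene(s) absent from calibration map: {missing[:10]}")
    absent = [g for g in genes if g not in ncounter_norm.index]
    if absent:
        raise KeyError(f"gene(s) absent from the nCounter matrix: {absent[:10]}")
    sub = ncounter_norm.loc[genes]
    b0 = cmap.table.loc[genes, "b0"].to_numpy()[:, None]
    b1 = cmap.table.loc[genes, "b1"].to_numpy()[:, None]
    pseudo = b0 + b1 * log_counts(sub.to_numpy(), cmap.log_offset)
    return pd.DataFrame(pseudo, index=genes, columns=sub.columns)


# ------------------------------------------------------------- panel design


def select_panel_genes(
    stats: pd.DataFrame,
    max_mean: float = 10_000.0,
    min_max: float = 100.0,
) -> list[str]:
    """Dynamic-range panel filter on per-gene raw count statistics.

    Drops genes that are excessively highly expressed (average count above
    ``max_mean``, which would dominate hybridisation) or barely expressed
    (maximum count below ``min_max``). ``stats`` needs ``mean`` and ``max``
    columns.
    """
    if not {"mean", "max"} <= set(stats.columns):
        raise ValueError("stats must have 'mean' and 'max' columns")
    keep = (stats["mean"] <= max_mean) & (stats["max"] >= min_max)
    return list(stats.index[keep])


# ------------------------------------------------------------ batch adjust


def batch_adjust(
    reference: pd.DataFrame,
    target: pd.DataFrame,
    eb: bool = True,
) -> pd.DataFrame:
    """Location-scale batch adjustment of ``target`` onto ``reference``.

    Per shared gene, target values are standardised by the target batch
    mean/sd and rescaled to the reference mean/sd. With ``eb``, per-gene
    batch location offsets and log scale ratios are shrunk towards their
    cross-gene means with precision weights estimated by moments — a
    simplified empirical-Bayes step in the spirit of reference-anchored
    ComBat. Zero-variance target genes get a location-only adjustment.
    """
    genes = [g for g in reference.index if g in target.index]
    if not genes:
        raise ValueError("no shared genes between reference and target")
    ref = reference.loc[genes].to_numpy(dtype=float)
    tgt = target.loc[genes].to_numpy(dtype=float)
    mu_r, sd_r = ref.mean(axis=1), ref.std(axis=1, ddof=1)
    mu_t, sd_t = tgt.mean(axis=1), tgt.std(axis=1, ddof=1)
    n_t = tgt.shape[1]

    gamma = mu_t - mu_r  # per-gene location offset
    with np.errstate(divide="ignore", invalid="ignore"):
        log_delta = np.where((sd_t > 0) & (sd_r > 0), np.log(sd_t / sd_r), 0.0)
    if eb and len(genes) > 2:
        gamma = _shrink(gamma, sd_t**2 / n_t)
        log_delta = _shrink(log_delta, np.full_like(log_delta, 1.0 / max(2 * (n_t - 1), 1)))
    delta = np.exp(log_delta)

    zero_sd = sd_t == 0
    if zero_sd.any():
        warnings.warn(
            f"{int(zero_sd.sum())} zero-variance target gene(s): location-only adjustment"
        )
    scale = np.where(zero_sd, 1.0, 1.0 / np.where(delta > 0, delta, 1.0))
    adjusted = (tgt - mu_t[:, None]) * scale[:, None] + (mu_t - gamma)[:, None]
    return pd.DataFrame(adjusted, index=genes, columns=target.columns)


def _shrink(est: np.ndarray, noise_var: np.ndarray) -> np.ndarray:
    """James-Stein style shrinkage of per-gene estimates toward their mean."""
    grand = est.mean()
    total_var = est.var(ddof=1)
    signal_var = max(total_var - noise_var.mean(), 0.0)
    weight = signal_var / np.maximum(signal_var + noise_var, 1e-12)
    return grand + weight * (est - grand)
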