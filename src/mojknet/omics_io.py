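"""Reading, cleaning, aligning and splitting multi-omics cohorts.

The cleaning cascade mirrors the cBioPortal-style preparation used for
TCGA Pan-Cancer cohorts:

1. sample identifiers truncated to the first 12 characters
   (``TCGA-CS-4938-01`` -> ``TCGA-CS-4938``), duplicates deduplicated
   keeping the *last* occurrence;
2. features with more than 10% missing values dropped, remaining missing
   entries imputed with zero;
3. features in which more than 10% of samples are zero (after imputation)
   dropped — near-constant features carry little discriminative signal;
4. samples lacking any of the four modalities, or lacking a subtype label
   in the clinical table, excluded;
5. the cohort sorted by sample id so every modality shares one row order.

Both thresholds are strict inequalities: a feature at exactly 10% is kept.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold, StratifiedShuffleSplit

from .datatypes import Modality, MultiOmicsDataset, OmicsMatrix, SplitPlan

__all__ = [
    "MISSING_TOKENS",
    "read_omics_table",
    "write_omics_table",
    "truncate_sample_ids",
    "dedup_keep_last",
    "filter_and_impute",
    "align_samples",
    "make_splits",
    "standardize_features",
    "write_bundle",
    "read_bundle",
]

#: Tokens treated as missing, both in omics bodies and in the clinical SUBTYPE
#: column.
MISSING_TOKENS = ("", "NA", "NaN", "nan", "[Not Available]")


def read_omics_table(
    path: str | Path,
    modality: Modality | str,
    sep: Optional[str] = None,
    samples_in_rows: bool = True,
) -> OmicsMatrix:
    """Read a delimited omics matrix into an :class:`OmicsMatrix`.

    Parameters
    ----------
    path
        Delimited text file. First column holds row identifiers, header row
        holds column identifiers.
    modality
        Which molecular layer the file contains.
    sep
        Field delimiter; ``None`` sniffs tab vs comma from the header line.
    samples_in_rows
        If False the file is transposed on read (cBioPortal ``data_*.txt``
        exports put genes in rows, samples in columns).

    Missing-value tokens (empty, ``NA``, ``NaN``) become NaN in ``values``
    and are flagged in ``missing_mask``. Any other non-numeric cell is an
    error, as is a duplicated feature id or an empty file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty omics file: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if sep is None:
        sep = "\t" if header.count("\t") >= header.count(",") else ","
    header_ids = header.split(sep)[1:]
    if samples_in_rows and len(header_ids) != len(set(header_ids)):
        dupes = sorted({h for h in header_ids if header_ids.count(h) > 1})
        raise ValueError(f"duplicate feature ids in {path}: {dupes}")
    df = pd.read_csv(
        path, sep=sep, index_col=0, dtype=str, keep_default_na=False, comment=None
    )
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"no data rows/columns in {path}")
    if not samples_in_rows:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.columns.duplicated().any():
        dupes = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValueError(f"duplicate feature ids in {path}: {dupes}")

    raw = df.to_numpy()
    missing = np.isin(np.char.strip(raw.astype(str)), MISSING_TOKENS)
    values = np.full(raw.shape, np.nan, dtype=np.float64)
    present = ~missing
    try:
        values[present] = np.asarray(raw[present], dtype=np.float64)
    except ValueError:
        # locate the offending cell for a useful message
        for (i, j), cell in np.ndenumerate(raw):
            if not missing[i, j]:
                try:
                    float(cell)
                except ValueError:
                    raise ValueError(
                        f"non-numeric cell {cell!r} at row {df.index[i]!r}, "
                        f"column {df.columns[j]!r} in {path}"
                    ) from None
        raise
    return OmicsMatrix(
        modality=Modality(modality),
        sample_ids=list(df.index),
        feature_ids=list(df.columns),
        values=values,
        missing_mask=missing,
    )


def write_omics_table(matrix: OmicsMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write an omics matrix as delimited text (samples in rows).

    Missing cells (per ``missing_mask``) are written as ``NA`` so the file
    round-trips through :func:`read_omics_table`.
    """
    df = pd.DataFrame(
        matrix.values, index=matrix.sample_ids, columns=matrix.feature_ids
    ).astype(object)
    df = df.mask(pd.DataFrame(matrix.missing_mask, index=df.index, columns=df.columns), "NA")
    df.index.name = "SAMPLE_ID"
    df.to_csv(path, sep=sep)


def truncate_sample_ids(ids: Sequence[str]) -> list[str]:
    """Truncate each sample id to its first 12 characters.

    Ids shorter than 12 characters pass through unchanged. Truncation must
    be applied *after* deduplication; if two distinct input ids collide
    after truncation this raises with the colliding ids listed.
    """
    out = [s[:12] for s in ids]
    seen: dict[str, str] = {}
    collisions = []
    for orig, trunc in zip(ids, out):
        if trunc in seen and seen[trunc] != orig:
            collisions.append((seen[trunc], orig))
        seen.setdefault(trunc, orig)
    if collisions:
        raise ValueError(f"sample ids collide after 12-char truncation: {collisions}")
    return out


def dedup_keep_last(matrix: OmicsMatrix) -> OmicsMatrix:
    """Drop duplicated (post-truncation) sample rows, retaining the last occurrence."""
    trunc = [s[:12] for s in matrix.sample_ids]
    last: dict[str, int] = {s: i for i, s in enumerate(trunc)}
    keep = sorted(last.values())
    return OmicsMatrix(
        modality=matrix.modality,
        sample_ids=[trunc[i] for i in keep],
        feature_ids=list(matrix.feature_ids),
        values=matrix.values[keep].copy(),
        missing_mask=matrix.missing_mask[keep].copy(),
    )


def filter_and_impute(
    matrix: OmicsMatrix, missing_frac: float = 0.10, zero_frac: float = 0.10
) -> OmicsMatrix:
    """Apply the missing-value and zero-fraction feature filters.

    Order is fixed: (1) drop features whose missing fraction is strictly
    greater than ``missing_frac``; (2) impute remaining missing cells with
    zero; (3) drop features whose zero fraction after imputation is strictly
    greater than ``zero_frac``. Surviving feature order is preserved and the
    result contains no missing values.
    """
    if not (0 < missing_frac <= 1) or not (0 < zero_frac <= 1):
        raise ValueError("missing_frac and zero_frac must lie in (0, 1]")
    n = matrix.n_samples
    miss = matrix.missing_mask.mean(axis=0)
    keep1 = miss <= missing_frac
    values = matrix.values[:, keep1].copy()
    mask = matrix.missing_mask[:, keep1]
    values[mask] = 0.0
    zfrac = (values == 0.0).mean(axis=0)
    keep2 = zfrac <= zero_frac
    if not keep2.any():
        raise ValueError(
            f"all {matrix.n_features} features of {matrix.modality.value} "
            "removed by the missing/zero filters"
        )
    feat1 = [f for f, k in zip(matrix.feature_ids, keep1) if k]
    feat2 = [f for f, k in zip(feat1, keep2) if k]
    return OmicsMatrix(
        modality=matrix.modality,
        sample_ids=list(matrix.sample_ids),
        feature_ids=feat2,
        values=values[:, keep2],
        missing_mask=np.zeros((n, int(keep2.sum())), dtype=bool),
    )


def _parse_event(status: object) -> Optional[int]:
    """Map an overall-survival status token to 0/1 (1 = deceased)."""
    s = str(status).strip()
    if s in MISSING_TOKENS:
        return None
    s_up = s.upper()
    if "DECEASED" in s_up or s_up in {"1", "1.0"}:
        return 1
    if "LIVING" in s_up or s_up in {"0", "0.0"}:
        return 0
    return None


def align_samples(
    matrices: Iterable[OmicsMatrix], clinical: pd.DataFrame
) -> MultiOmicsDataset:
    """Intersect modalities with the labeled clinical table into one cohort.

    Keeps samples present in *all* supplied modalities and carrying a
    non-missing SUBTYPE in ``clinical`` (columns ``PATIENT_ID``, ``SUBTYPE``
    and optionally ``OS_MONTHS`` / ``OS_STATUS``). Output is sorted by
    sample id; survival is attached for samples where both time and event
    parse. Sample ids must already be truncated and deduplicated.
    """
    matrices = list(matrices)
    clin = clinical.copy()
    clin["PATIENT_ID"] = clin["PATIENT_ID"].astype(str)
    subtype = clin["SUBTYPE"].astype(str).str.strip()
    labeled = clin.loc[~subtype.isin(MISSING_TOKENS)]
    labeled = labeled.drop_duplicates(subset="PATIENT_ID", keep="last")
    labeled = labeled.set_index("PATIENT_ID")

    shared: set[str] = set(labeled.index)
    for mat in matrices:
        shared &= set(mat.sample_ids)
    if not shared:
        raise ValueError("no samples shared by all modalities and the clinical table")
    ids = sorted(shared)

    class_names = sorted(labeled.loc[ids, "SUBTYPE"].astype(str).str.strip().unique())
    code = {c: i for i, c in enumerate(class_names)}
    labels = pd.Series(
        [code[str(labeled.at[s, "SUBTYPE"]).strip()] for s in ids], index=ids, dtype=np.int64
    )

    survival = None
    if {"OS_MONTHS", "OS_STATUS"} <= set(labeled.columns):
        times, events, ok = [], [], []
        for s in ids:
            ev = _parse_event(labeled.at[s, "OS_STATUS"])
            try:
                t = float(labeled.at[s, "OS_MONTHS"])
            except (TypeError, ValueError):
                t = np.nan
            good = ev is not None and np.isfinite(t) and t > 0
            times.append(t if good else np.nan)
            events.append(ev if ev is not None else 0)
            ok.append(good)
        if any(ok):
            survival = pd.DataFrame(
                {"time": times, "event": events, "observed": ok}, index=ids
            )

    omics = {m.modality: m.subset_samples(ids) for m in matrices}
    return MultiOmicsDataset(
        omics=omics, labels=labels, sample_ids=ids, survival=survival,
        class_names=class_names,
    )


def make_splits(
    dataset: MultiOmicsDataset,
    n_folds: int = 5,
    seed: int = 0,
    stratified: bool = True,
    holdout: bool = False,
    test_size: float = 0.25,
) -> SplitPlan:
    """Build a deterministic evaluation split.

    Default is stratified k-fold cross-validation. With ``holdout=True`` a
    single stratified train/test split is produced instead (default 75/25),
    encoded as fold 0 = train, fold 1 = test.
    """
    y = dataset.y
    n = len(y)
    if holdout:
        splitter = StratifiedShuffleSplit(
            n_splits=1, test_size=test_size, random_state=seed
        )
        (_, test_idx), = splitter.split(np.zeros(n), y)
        fold_of = np.zeros(n, dtype=np.int64)
        fold_of[test_idx] = 1
        return SplitPlan(n_folds=2, fold_of=fold_of, stratified=True, seed=seed,
                         kind="holdout")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds n_samples={n}")
    if stratified:
        kf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = kf.split(np.zeros(n), y)
    else:
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = kf.split(np.zeros(n))
    fold_of = np.empty(n, dtype=np.int64)
    for fold, (_, test_idx) in enumerate(splits):
        fold_of[test_idx] = fold
    return SplitPlan(n_folds=n_folds, fold_of=fold_of, stratified=stratified, seed=seed)


def standardize_features(train: OmicsMatrix, apply_to: OmicsMatrix) -> OmicsMatrix:
    """Z-score ``apply_to`` using per-feature mean/sd fitted on ``train``.

    Population standard deviation (ddof=0); features constant on the
    training rows map to all zeros. Fitting on the training fold only keeps
    test-fold feature statistics out of the model.
    """
    if list(train.feature_ids) != list(apply_to.feature_ids):
        raise ValueError("train and apply_to must share feature_ids")
    mean = train.values.mean(axis=0)
    sd = train.values.std(axis=0, ddof=0)
    safe = np.where(sd > 0, sd, 1.0)
    values = (apply_to.values - mean) / safe
    values[:, sd == 0] = 0.0
    return OmicsMatrix(
        modality=apply_to.modality,
        sample_ids=list(apply_to.sample_ids),
        feature_ids=list(apply_to.feature_ids),
        values=values,
        missing_mask=np.zeros_like(apply_to.missing_mask),
    )


# ---------------------------------------------------------------------------
# dataset bundle (directory of delimited text files + manifest)

_BUNDLE_FILES = {
    Modality.CNA: "cna.tsv",
    Modality.MET: "methylation.tsv",
    Modality.MRNA: "mrna.tsv",
    Modality.RPPA: "rppa.tsv",
}


def write_bundle(dataset: MultiOmicsDataset, outdir: str | Path,
                 provenance: Optional[dict] = None) -> Path:
    """Write an aligned cohort as a directory of delimited text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for mod, fname in _BUNDLE_FILES.items():
        if mod in dataset.omics:
            write_omics_table(dataset.omics[mod], outdir / fname)
    labels = pd.DataFrame({
        "SAMPLE_ID": dataset.sample_ids,
        "SUBTYPE": [
            dataset.class_names[c] if dataset.class_names else str(c)
            for c in dataset.y
        ],
        "CLASS_CODE": dataset.y,
    })
    labels.to_csv(outdir / "labels.tsv", sep="\t", index=False)
    if dataset.survival is not None:
        surv = dataset.survival.copy()
        surv.index.name = "SAMPLE_ID"
        surv.to_csv(outdir / "survival.tsv", sep="\t")
    manifest = {
        "n_samples": dataset.n_samples,
        "n_classes": dataset.n_classes,
        "class_names": dataset.class_names,
        "feature_counts": {m.value: dataset.omics[m].n_features for m in dataset.omics},
        "has_survival": dataset.survival is not None,
    }
    if provenance:
        manifest["provenance"] = provenance
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def read_bundle(indir: str | Path) -> MultiOmicsDataset:
    """Read a cohort bundle written by :func:`write_bundle`."""
    indir = Path(indir)
    omics = {}
    for mod, fname in _BUNDLE_FILES.items():
        path = indir / fname
        if path.exists():
            omics[mod] = read_omics_table(path, mod, sep="\t")
    labels_df = pd.read_csv(indir / "labels.tsv", sep="\t", dtype={"SAMPLE_ID": str})
    ids = list(labels_df["SAMPLE_ID"])
    labels = pd.Series(labels_df["CLASS_CODE"].to_numpy(np.int64), index=ids)
    class_names = None
    if "SUBTYPE" in labels_df:
        order = labels_df.drop_duplicates("CLASS_CODE").sort_values("CLASS_CODE")
        class_names = [str(s) for s in order["SUBTYPE"]]
    survival = None
    surv_path = indir / "survival.tsv"
    if surv_path.exists():
        survival = pd.read_csv(surv_path, sep="\t", index_col="SAMPLE_ID")
        survival.index = survival.index.astype(str)
        survival = survival.loc[ids]
    omics = {m: mat.subset_samples(ids) for m, mat in omics.items()}
    return MultiOmicsDataset(
        omics=omics, labels=labels, sample_ids=ids, survival=survival,
        class_names=class_names,
    )
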