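"""Experimental protocol: contrasts, stratified splits, repeated LVQ runs,
accuracy summaries (mean ± sd, coefficient of variance) and report tables.

Two pairwise contrasts are evaluated per incubation day: N/D (non-developed
vs developed embryo) and D/W (developed vs weakly developed), each with a
single scalar input feature — the spectral mean-peak x̄ or the morphologic
rate W.  A run draws a stratified two-thirds/one-third train/test split,
trains an LVQ2.1 network (n = 1, l = 2, m = 10) and records training
("modeling") and testing ("prediction") accuracy; five runs are summarised
as mean ± sample sd with the coefficient of variance cv = s/μ (reported as
a half-up-rounded integer percentage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import phantom as ph
from .bands import flatten_pixels, pca, select_optimal_wavelengths
from .envi import band_index, calibrate
from .features import mean_peak_at_band, select_roi
from .lvq import TrainConfig, init_codebooks, predict, size_competitive_layer, train_lvq21
from .segmentation import adaptive_embryo_threshold, egg_mask, morph_rate

__all__ = ["SplitSpec", "RunSummary", "make_contrast", "split",
           "coefficient_of_variance", "summarize_accuracies", "run_experiment",
           "build_report", "report_to_tsv", "report_from_tsv",
           "extract_cohort_features", "run_full_evaluation",
           "SPECTRAL_FEATURE", "MORPH_FEATURE", "CONTRASTS"]

SPECTRAL_FEATURE = "spectral_mean_peak"
MORPH_FEATURE = "morph_rate_W"
CONTRASTS = (("N", "D"), ("D", "W"))


@dataclass(frozen=True)
class SplitSpec:
    train_ids: tuple
    test_ids: tuple
    seed: int
    stratified: bool = True

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


@dataclass(frozen=True)
class RunSummary:
    """Per-run accuracies (fractions) and their summary statistics."""

    train_accuracies: tuple
    test_accuracies: tuple
    train_mean: float
    train_sd: float
    train_cv: int
    test_mean: float
    test_sd: float
    test_cv: int


def make_contrast(rows: pd.DataFrame, day: int,
                  contrast: tuple[str, str]) -> pd.DataFrame:
    """Rows of one day restricted to the two contrast groups.

    ``rows`` must carry columns id, day, group and value.  Both groups must
    be present at that day.
    """
    a, b = contrast
    subset = rows[(rows["day"] == day) & (rows["group"].isin([a, b]))]
    for group in contrast:
        if not (subset["group"] == group).any():
            raise ValueError(f"group {group} missing at day {day}")
    return subset.reset_index(drop=True)


def split(dataset: pd.DataFrame, seed: int) -> SplitSpec:
    """Stratified 2/3 train / 1/3 test split of egg ids.

    Per group, floor(2n/3) shuffled ids go to training and the remainder
    to testing; deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    train: list = []
    test: list = []
    for group in sorted(dataset["group"].unique()):
        ids = dataset.loc[dataset["group"] == group, "id"].to_numpy()
        if ids.size < 3:
            raise ValueError(f"group {group} has {ids.size} samples; need >= 3")
        perm = rng.permutation(ids.size)
        n_train = (2 * ids.size) // 3
        train.extend(ids[perm[:n_train]])
        test.extend(ids[perm[n_train:]])
    return SplitSpec(train_ids=tuple(train), test_ids=tuple(test), seed=seed)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def coefficient_of_variance(mean: float, sd: float) -> int:
    """cv = s/μ, returned as a half-up-rounded integer percentage.

    Works identically whether mean and sd are on the fraction or the
    percent scale (the ratio is scale-free).
    """
    if mean <= 0:
        raise ValueError("cv requires a positive mean")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return _round_half_up(100.0 * sd / mean)


def summarize_accuracies(train_accs, test_accs) -> RunSummary:
    """Mean, sample sd (ddof = 1) and cv over repeated-run accuracies."""
    tr = np.asarray(train_accs, dtype=float)
    te = np.asarray(test_accs, dtype=float)
    if tr.size < 2 or te.size < 2:
        raise ValueError("need >= 2 runs to summarise")
    tr_mean, te_mean = tr.mean(), te.mean()
    tr_sd, te_sd = tr.std(ddof=1), te.std(ddof=1)
    return RunSummary(
        train_accuracies=tuple(tr), test_accuracies=tuple(te),
        train_mean=float(tr_mean), train_sd=float(tr_sd),
        train_cv=coefficient_of_variance(tr_mean, tr_sd),
        test_mean=float(te_mean), test_sd=float(te_sd),
        test_cv=coefficient_of_variance(te_mean, te_sd),
    )


def run_experiment(dataset: pd.DataFrame, n_runs: int = 5,
                   config: TrainConfig | None = None, seed: int = 0,
                   architecture_offset: int = 8,
                   refresh_split: bool = True) -> RunSummary:
    """n_runs independent split + train + test cycles on one contrast dataset.

    Each run draws a fresh stratified split (or reuses the first split when
    ``refresh_split`` is false) and a fresh codebook initialisation, so the
    summary captures both sources of run-to-run variance.
    """
    config = config or TrainConfig()
    groups = sorted(dataset["group"].unique())
    if len(groups) != 2:
        raise ValueError("run_experiment expects a binary contrast dataset")
    m = size_competitive_layer(n=1, l=2, a=architecture_offset)

    by_id = dataset.set_index("id")
    train_accs, test_accs = [], []
    first_split = None
    for run in range(n_runs):
        run_seed = int(np.random.SeedSequence([int(seed), run]).generate_state(1)[0]
                       % 2**31)
        if refresh_split or first_split is None:
            sp = split(dataset, run_seed)
            if first_split is None:
                first_split = sp
        else:
            sp = first_split
        tr = by_id.loc[list(sp.train_ids)]
        te = by_id.loc[list(sp.test_ids)]
        model = init_codebooks(tr["value"].to_numpy(), tr["group"].to_numpy(),
                               m=m, seed=run_seed)
        run_config = TrainConfig(learning_rate=config.learning_rate,
                                 error_goal=config.error_goal,
                                 max_epochs=config.max_epochs,
                                 window=config.window, seed=run_seed)
        train_lvq21(model, tr["value"].to_numpy(), tr["group"].to_numpy(),
                    run_config)
        train_accs.append(float(np.mean(
            predict(model, tr["value"].to_numpy()) == tr["group"].to_numpy())))
        test_accs.append(float(np.mean(
            predict(model, te["value"].to_numpy()) == te["group"].to_numpy())))
    return RunSummary(**summarize_accuracies(train_accs, test_accs).__dict__)


# ---------------------------------------------------------------------------
# report tables


def _cell(mean: float, sd: float) -> str:
    return f"{_round_half_up(100 * mean)}±{_round_half_up(100 * sd)}"


def build_report(summaries: dict) -> dict[str, pd.DataFrame]:
    """One table per feature: rows = days, columns = modeling/prediction
    accuracy (percent, mean±sd) and cv for each contrast.

    ``summaries`` maps (feature_name, contrast, day) -> RunSummary.
    Missing cells appear as 'NA' gaps rather than raising.
    """
    features = sorted({key[0] for key in summaries})
    tables = {}
    for feat in features:
        rows = []
        for day in ph.DAYS:
            row: dict = {"day": f"Day {day}"}
            for contrast in CONTRASTS:
                tag = "/".join(contrast)
                s = summaries.get((feat, contrast, day))
                if s is None:
                    row[f"{tag} modeling"] = "NA"
                    row[f"{tag} modeling cv"] = "NA"
                    row[f"{tag} prediction"] = "NA"
                    row[f"{tag} prediction cv"] = "NA"
                else:
                    row[f"{tag} modeling"] = _cell(s.train_mean, s.train_sd)
                    row[f"{tag} modeling cv"] = str(s.train_cv)
                    row[f"{tag} prediction"] = _cell(s.test_mean, s.test_sd)
                    row[f"{tag} prediction cv"] = str(s.test_cv)
            rows.append(row)
        tables[feat] = pd.DataFrame(rows)
    return tables


def report_to_tsv(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


def report_from_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


# ---------------------------------------------------------------------------
# end-to-end feature extraction over a phantom cohort


def select_feature_band(cfg: ph.PhantomConfig, seed_offset: int = 0) -> int:
    """Band index for the spectral feature, chosen by PCA on one cohort cube.

    Runs the band-selection chain (calibrate -> egg mask -> pixel PCA ->
    PC1 loading extremum) on the first developed egg at the last day, where
    spectral structure is strongest.
    """
    records = ph.cohort_records(cfg)
    ref = ph.generate_references(cfg)
    rec = next((r for r in records if r[1] == "D"), records[0])
    cube, _ = ph.generate_phantom_cube(cfg, rec[1], ph.DAYS[-1], rec[3])
    cal = calibrate(cube, ref)
    egg = egg_mask(cal)
    result = pca(flatten_pixels(cal, egg.values))
    selected = select_optimal_wavelengths(result, cal.grid, component=1,
                                          max_bands=1)
    return band_index(cal.grid, selected.wavelengths[0])


def extract_cohort_features(cfg: ph.PhantomConfig, roi_size: int = 1000,
                            window: int = 51, feature_band: int | None = None,
                            segmentation_wavelength: float = 825.0,
                            ) -> pd.DataFrame:
    """Long-format feature table (id, day, group, feature_name, value).

    Generates each cohort cube in memory, calibrates it and extracts both
    scalar features: the spectral mean-peak x̄ at the PCA-selected band and
    the morphologic rate W from the two-stage segmentation.
    """
    ref = ph.generate_references(cfg)
    if feature_band is None:
        feature_band = select_feature_band(cfg)
    rows = []
    for egg_id, group, _idx, seed in ph.cohort_records(cfg):
        for day in ph.DAYS:
            cube, _truth = ph.generate_phantom_cube(cfg, group, day, seed)
            cal = calibrate(cube, ref)
            egg = egg_mask(cal, band_wavelength=segmentation_wavelength)
            roi = select_roi(cal, egg.values, target_size=roi_size)
            x_bar = mean_peak_at_band(cal, roi, feature_band)
            embryo = adaptive_embryo_threshold(
                cal, egg, band_wavelength=segmentation_wavelength, window=window)
            w = morph_rate(embryo, egg).W
            rows.append({"id": egg_id, "day": day, "group": group,
                         "feature_name": SPECTRAL_FEATURE, "value": x_bar})
            rows.append({"id": egg_id, "day": day, "group": group,
                         "feature_name": MORPH_FEATURE, "value": w})
    return pd.DataFrame(rows,
                        columns=["id", "day", "group", "feature_name", "value"])


def run_full_evaluation(features: pd.DataFrame, n_runs: int = 5,
                        seed: int = 0,
                        config: TrainConfig | None = None) -> dict:
    """Repeated-run LVQ evaluation of every (feature, contrast, day) cell.

    Returns {(feature_name, contrast, day): RunSummary}; feed the result to
    :func:`build_report` for the tabular view.
    """
    summaries = {}
    feature_names = sorted(features["feature_name"].unique())
    for feat_idx, feat in enumerate(feature_names):
        feat_rows = features[features["feature_name"] == feat]
        for contrast in CONTRASTS:
            for day in ph.DAYS:
                try:
                    dataset = make_contrast(feat_rows, day, contrast)
                except ValueError:
                    continue
                cell_seed = int(
                    np.random.SeedSequence(
                        [int(seed), feat_idx,
                         ph.DAYS.index(day), CONTRASTS.index(contrast)]
                    ).generate_state(1)[0] % 2**31)
                summaries[(feat, contrast, day)] = run_experiment(
                    dataset, n_runs=n_runs, config=config, seed=cell_seed)
    return summaries
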