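"""Global differential-binding model: feature table, LASSO fit, reports.

The model predicts the class of each aligned sequence from
P(1|s) = sigmoid(a*DM(s) + sum_i b_i*NE_i(s) + sum_j c_j*CF_j(s)),
fitted with an L1 penalty so that only the most relevant variables keep
nonzero coefficients. Feature discovery (PWM-version choice, DM fit, NE and
CF region selection) uses the 70% training rows only; accuracy is the AUROC
on the held-out 30%. Group ablations zero a coefficient group without
retraining; the importance profile is the 3-vector of test-AUROC losses from
ablating DM, NE and CF in turn.

`DifferentialBindingModel` holds the inputs and configuration; `.fit(seed)`
runs the pipeline and returns a `DifferentialBindingResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import cf as cf_mod
from . import dm as dm_mod
from . import ne as ne_mod
from .glm import (LassoLogisticFit, _lambda_max, binomial_deviance,
                  lasso_logistic_cv, lasso_logistic_path)
from .motifs import (PPM, PWM, AlignedSequence, estimate_class_ppms, mask_core,
                     ppm_to_pwm, score_threshold, select_pwm_version)
from .peaks import rebalance
from .regions import Region
from .stats import auroc

__all__ = [
    "FeatureTable", "FittedModel", "DifferentialBindingModel",
    "DifferentialBindingResults", "ModelConfig", "split_train_test",
    "fit_global", "ablate", "variable_importance", "cluster_importance_profiles",
]

GROUPS = ("DM", "NE", "CF")


@dataclass
class ModelConfig:
    halfwidth: int = 500
    n_flank: int = 4
    hit_pvalue: float = 1e-4
    background: tuple = (0.25, 0.25, 0.25, 0.25)
    pseudocount: float = 0.01
    orient_minus_strand: bool = True
    ne_bins: int = 7
    ne_max_k: int = 4
    ne_min_gain: float = 0.01
    ne_include_seeds: bool = False
    use_ne: bool = True  # off: core-motif + co-factor model only
    cf_bins: int = 13
    train_fraction: float = 0.70
    n_folds: int = 10
    lambda_rule_global: str = "1se"
    lambda_rule_dm: str = "min"
    n_keep: int = 10
    top_n: int = 15


@dataclass
class FeatureTable:
    """Design matrix of the global model plus per-row and per-column metadata."""

    values: pd.DataFrame  # rows = sequences, columns = features
    labels: np.ndarray  # 1 = class 1
    split: np.ndarray  # True = train
    column_meta: pd.DataFrame  # name, group, identity, region_start, region_end

    def __post_init__(self):
        assert len(self.values) == len(self.labels) == len(self.split)
        assert list(self.values.columns) == list(self.column_meta["name"])
        assert not self.values.isna().any().any()

    @property
    def train(self) -> np.ndarray:
        return self.split

    def groups(self) -> np.ndarray:
        return self.column_meta["group"].to_numpy()


@dataclass
class FittedModel:
    """Standardized-scale coefficients of the global L1 fit."""

    columns: list
    groups: np.ndarray
    coef: np.ndarray  # standardized scale; 0 for dropped/constant columns
    intercept: float
    mean: np.ndarray  # training means
    scale: np.ndarray  # training sds (1 for constant columns)
    lambda_: float
    cv: LassoLogisticFit
    dropped_constant: list = field(default_factory=list)

    def standardize(self, values: pd.DataFrame) -> np.ndarray:
        return (values.to_numpy(dtype=float) - self.mean) / self.scale

    def linear_scores(self, values: pd.DataFrame, coef: np.ndarray | None = None,
                      intercept: float | None = None) -> np.ndarray:
        coef = self.coef if coef is None else coef
        intercept = self.intercept if intercept is None else intercept
        return self.standardize(values) @ coef + intercept

    @property
    def nonzero(self) -> int:
        return int((self.coef != 0).sum())


def split_train_test(labels, train_fraction: float = 0.70, seed: int = 0) -> np.ndarray:
    """Stratified train/test assignment; True marks training rows."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train = np.zeros(labels.size, dtype=bool)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError("each class needs at least 2 sequences")
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train[rng.choice(idx, size=n_train, replace=False)] = True
    return train


def fit_global(table: FeatureTable, seed: int = 0, rule: str = "1se",
               n_folds: int = 10) -> FittedModel:
    """L1-penalized logistic fit of the assembled table on its training rows.

    Columns are standardized to training mean 0 / sd 1 (heterogeneous scales:
    motif scores vs. k-mer frequencies); constant training columns are
    dropped (coefficient pinned at 0) with a warning.
    """
    import warnings

    X = table.values.to_numpy(dtype=float)
    tr = table.train
    mean = X[tr].mean(axis=0)
    sd = X[tr].std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"dropping constant columns: {list(table.values.columns[const])}")
    scale = np.where(const, 1.0, sd)
    Xs = (X - mean) / scale
    keep = ~const
    fit = lasso_logistic_cv(Xs[tr][:, keep], table.labels[tr].astype(float),
                            seed=seed, n_folds=n_folds, rule=rule)
    coef = np.zeros(X.shape[1])
    coef[keep] = fit.coef
    # re-embed the CV path into full-width coefficient vectors
    path = np.zeros((len(fit.lambdas), X.shape[1]))
    path[:, keep] = fit.path_coefs
    fit.path_coefs = path
    return FittedModel(list(table.values.columns), table.groups(), coef,
                       fit.intercept, mean, scale, fit.lambda_, fit,
                       dropped_constant=list(table.values.columns[const]))


def _standardize_train(values: pd.DataFrame, train: np.ndarray):
    X = values.to_numpy(dtype=float)
    mean = X[train].mean(axis=0)
    sd = X[train].std(axis=0)
    const = sd == 0
    scale = np.where(const, 1.0, sd)
    return (X - mean) / scale, mean, scale, const


def fit_global_nested(table: FeatureTable, discover_values, seed: int = 0,
                      rule: str = "1se", n_folds: int = 10,
                      n_lambdas: int = 30, lambda_min_ratio: float = 1e-2,
                      ) -> FittedModel:
    """Global L1 fit with feature discovery nested inside the lambda CV.

    (k-mer, region) and (PWM, region) variables are *selected* to separate
    the training labels, so a lambda CV run against the same rows inherits
    that selection optimism and keeps noise variables. Here
    `discover_values(fold_train_mask)` re-runs the discovery using only the
    fold's training rows and returns the re-discovered feature values for
    all rows; each fold's deviance is therefore measured on rows the
    selection never saw, and on label-free data the cross-validated optimum
    stays at the empty model.
    """
    from sklearn.model_selection import StratifiedKFold

    y = table.labels.astype(float)
    tr_rows = np.flatnonzero(table.train)
    Xs, mean, scale, const = _standardize_train(table.values, table.train)
    keep = ~const
    lmax = max(_lambda_max(Xs[tr_rows][:, keep], y[tr_rows]), 1e-12)
    lambdas = np.geomspace(lmax * 1.0001, lmax * lambda_min_ratio, n_lambdas)

    n_folds = min(n_folds, int(np.bincount(table.labels[tr_rows]).min()))
    skf = StratifiedKFold(n_splits=max(n_folds, 2), shuffle=True,
                          random_state=seed)
    dev = np.zeros((skf.get_n_splits(), len(lambdas)))
    for f, (itr, ite) in enumerate(skf.split(tr_rows, y[tr_rows])):
        fmask = np.zeros(len(y), dtype=bool)
        fmask[tr_rows[itr]] = True
        vals = discover_values(fmask)
        Xf, _, _, cf_const = _standardize_train(vals, fmask)
        Xf = Xf[:, ~cf_const]
        te_rows = tr_rows[ite]
        _, coefs, icepts = lasso_logistic_path(Xf[fmask], y[fmask],
                                               lambdas=lambdas)
        for i in range(len(lambdas)):
            dev[f, i] = binomial_deviance(Xf[te_rows], y[te_rows],
                                          coefs[i], icepts[i])
    mean_dev = dev.mean(axis=0)
    se = dev.std(axis=0, ddof=1) / np.sqrt(dev.shape[0])
    i_min = int(np.argmin(mean_dev))
    if rule == "min":
        i_sel = i_min
    elif rule == "1se":
        i_sel = int(np.flatnonzero(mean_dev <= mean_dev[i_min] + se[i_min])[0])
    else:
        raise ValueError(f"unknown lambda rule {rule!r}")

    _, path, icepts = lasso_logistic_path(Xs[tr_rows][:, keep], y[tr_rows],
                                          lambdas=lambdas)
    full_path = np.zeros((len(lambdas), Xs.shape[1]))
    full_path[:, keep] = path
    coef = full_path[i_sel].copy()
    cv = LassoLogisticFit(coef[keep].copy(), float(icepts[i_sel]),
                          float(lambdas[i_sel]), lambdas, full_path, icepts,
                          mean_dev, se, rule)
    return FittedModel(list(table.values.columns), table.groups(), coef,
                       float(icepts[i_sel]), mean, scale, float(lambdas[i_sel]),
                       cv, dropped_constant=list(table.values.columns[const]))


def ablate(model: FittedModel, table: FeatureTable, group: str) -> float:
    """Test AUROC after zeroing one coefficient group (no retraining)."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    coef = model.coef.copy()
    coef[model.groups == group] = 0.0
    te = ~table.train
    return auroc(model.linear_scores(table.values, coef)[te], table.labels[te])


def variable_importance(model: FittedModel, table: FeatureTable,
                        n_keep: int = 10) -> pd.DataFrame:
    """Per-variable importance at the path model with ~n_keep nonzero terms.

    The regularization path point whose nonzero count is closest to `n_keep`
    (exactly n_keep when attained) defines a compact model; the importance
    of each variable X is the test-AUROC drop from zeroing its coefficient
    in that model. Variables with a zero coefficient there have importance
    exactly 0 and are omitted. Ranked descending.
    """
    import warnings

    nz = (model.cv.path_coefs != 0).sum(axis=1)
    if nz.max() < n_keep:
        warnings.warn(f"path never reaches {n_keep} nonzero terms; "
                      f"using the densest model ({nz.max()})")
    i = int(np.argmin(np.abs(nz - n_keep)))
    coef = model.cv.path_coefs[i]
    intercept = float(model.cv.path_intercepts[i])
    te = ~table.train
    y_te = table.labels[te]
    vals = table.values
    full = auroc(model.linear_scores(vals, coef, intercept)[te], y_te)
    rows = []
    for j in np.flatnonzero(coef):
        c = coef.copy()
        c[j] = 0.0
        a = auroc(model.linear_scores(vals, c, intercept)[te], y_te)
        meta = table.column_meta.iloc[j]
        rows.append({"name": meta["name"], "group": meta["group"],
                     "identity": meta["identity"],
                     "region_start": meta["region_start"],
                     "region_end": meta["region_end"],
                     "coef": float(coef[j]),
                     "associated_class": 1 if coef[j] > 0 else 2,
                     "delta_auroc": full - a})
    cols = ["name", "group", "identity", "region_start", "region_end",
            "coef", "associated_class", "delta_auroc"]
    if not rows:
        return pd.DataFrame(columns=cols + ["rank"])
    out = pd.DataFrame(rows).sort_values("delta_auroc", ascending=False,
                                         kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def cluster_importance_profiles(profiles, k: int = 3, seed: int = 0,
                                elbow_range: range = range(1, 7)):
    """K-means over 3-vector importance profiles; also emits an elbow curve.

    Returns (labels, centroids, elbow) where elbow is a list of
    (k, total within-cluster variance).
    """
    from sklearn.cluster import KMeans

    P = np.asarray(profiles, dtype=float)
    if len(P) < k:
        raise ValueError("fewer profiles than clusters")
    km = KMeans(n_clusters=k, n_init=25, random_state=seed).fit(P)
    elbow = []
    for kk in elbow_range:
        if kk > len(P):
            break
        elbow.append((kk, float(KMeans(n_clusters=kk, n_init=10,
                                       random_state=seed).fit(P).inertia_)))
    return km.labels_, km.cluster_centers_, elbow


# ---------------------------------------------------------------------------


def _seed_stream(seed: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(8) % (2**31)]


class DifferentialBindingModel:
    """Two-class differential binding model over ChIP-seq peak sequences.

    Construct from raw summit-centered windows (`__init__` /
    :meth:`from_peaks`) or from already-aligned sequences
    (:meth:`from_aligned`); call :meth:`fit` to run sequence alignment,
    feature discovery and the global penalized fit.
    """

    def __init__(self, windows_a: list[str], windows_b: list[str],
                 target_versions: list[PPM] | None, library: list[PPM | PWM],
                 skip_anchoring: bool = False, config: ModelConfig | None = None):
        self.windows_a = list(windows_a)
        self.windows_b = list(windows_b)
        self.aligned = None
        self.aligned_labels = None
        self.target_versions = list(target_versions or [])
        self.config = config or ModelConfig()
        self.skip_anchoring = skip_anchoring or not self.target_versions
        self.library = [
            p if isinstance(p, PWM) else ppm_to_pwm(p, self.config.background,
                                                    self.config.pseudocount)
            for p in library
        ]

    @classmethod
    def from_aligned(cls, sequences: list[AlignedSequence], labels,
                     target_versions=None, library=(), config=None,
                     skip_anchoring: bool = False):
        """Build from pre-aligned 1-kb sequences (bypasses rebalance/anchor)."""
        m = cls([], [], target_versions, list(library),
                skip_anchoring=skip_anchoring, config=config)
        m.skip_anchoring = skip_anchoring
        m.aligned = list(sequences)
        m.aligned_labels = np.asarray(labels, dtype=int)
        return m

    @classmethod
    def from_peaks(cls, bed_a, bed_b, genome_fasta, target_motif=None, library=(),
                   mode: str = "unique-vs-unique", window_bp: int = 1000,
                   summit_column: int | None = None, skip_anchoring: bool = False,
                   config: ModelConfig | None = None):
        """Build from two BED files and a genome FASTA.

        `mode` selects the peak comparison: "unique-vs-unique" removes peaks
        common to the two experiments and compares the complements;
        "unique-a-vs-common" / "unique-b-vs-common" compare one complement
        with the intersection; "as-given" uses the files untouched.
        `target_motif` is a JASPAR file possibly holding several versions of
        the target TF's motif; `library` is an iterable of JASPAR files (or
        parsed PPM/PWM objects) for the co-factor search.
        """
        import pyfaidx

        from .motifs import read_jaspar
        from .peaks import extract_window, partition_peaks, read_bed

        cfg = config or ModelConfig()
        pa = read_bed(bed_a, summit_column=summit_column)
        pb = read_bed(bed_b, summit_column=summit_column)
        if mode == "unique-vs-unique":
            part = partition_peaks(pa, pb, window_bp)
            pa, pb = part.unique_a, part.unique_b
        elif mode == "unique-a-vs-common":
            part = partition_peaks(pa, pb, window_bp)
            pa, pb = part.unique_a, part.common
        elif mode == "unique-b-vs-common":
            part = partition_peaks(pa, pb, window_bp)
            pa, pb = part.unique_b, part.common
        elif mode != "as-given":
            raise ValueError(f"unknown mode {mode!r}")
        genome = pyfaidx.Fasta(str(genome_fasta)) if not hasattr(genome_fasta, "keys") \
            else genome_fasta
        # raw windows wide enough that any anchor within +-halfwidth of the
        # summit still yields a full 2*halfwidth aligned window
        raw_half = 2 * cfg.halfwidth
        wins = []
        for peaks in (pa, pb):
            ws = []
            for p in peaks:
                w = extract_window(genome, p.chrom, p.summit, raw_half)
                if w is not None:
                    ws.append(w)
            wins.append(ws)
        versions = None
        if target_motif is not None:
            versions = target_motif if isinstance(target_motif, list) else \
                read_jaspar(target_motif)
        libs = []
        for item in library:
            if isinstance(item, (PPM, PWM)):
                libs.append(item)
            else:
                libs.extend(read_jaspar(item))
        return cls(wins[0], wins[1], versions, libs,
                   skip_anchoring=skip_anchoring, config=cfg)

    # -- pipeline -----------------------------------------------------------

    def fit(self, seed: int = 0, split: np.ndarray | None = None,
            labels_override: np.ndarray | None = None) -> "DifferentialBindingResults":
        """Run the full pipeline under `seed` and return the results.

        `split`/`labels_override` allow injecting a fixed train/test
        assignment (and relabeled rows) for reproducibility audits; discovery
        only ever sees training rows.
        """
        cfg = self.config
        seeds = _seed_stream(seed)
        info: dict = {"seed": seed}

        if self.aligned is not None:
            aligned = list(self.aligned)
            labels = self.aligned_labels.copy()
            if labels_override is not None:
                labels = np.asarray(labels_override, dtype=int)
            if split is None:
                split = split_train_test(labels, cfg.train_fraction, seeds[1])
            split = np.asarray(split, dtype=bool)
            original_scores = None
            version_index = None
        else:
            wa, wb = rebalance(self.windows_a, self.windows_b, seeds[0])
            windows = list(wa) + list(wb)
            labels = np.r_[np.ones(len(wa), dtype=int), np.zeros(len(wb), dtype=int)]
            if labels_override is not None:
                labels = np.asarray(labels_override, dtype=int)
            if split is None:
                split = split_train_test(labels, cfg.train_fraction, seeds[1])
            split = np.asarray(split, dtype=bool)

            if self.skip_anchoring:
                original_scores = None
                aligned = []
                for w, l in zip(windows, labels):
                    summit = len(w) // 2
                    aligned.append(AlignedSequence(
                        w[summit - cfg.halfwidth: summit + cfg.halfwidth].upper(),
                        int(l)))
            else:
                from .motifs import anchor_peak_window
                tr_idx = np.flatnonzero(split)
                version_index, scan_pwm, version_auroc = select_pwm_version(
                    self.target_versions, [windows[i] for i in tr_idx],
                    labels[tr_idx], cfg.halfwidth, cfg.background, cfg.pseudocount)
                info["pwm_version"] = version_index
                info["pwm_version_train_auroc"] = version_auroc
                threshold = score_threshold(scan_pwm, cfg.hit_pvalue, cfg.background)
                info["hit_threshold"] = threshold
                aligned, keep = [], []
                for i, w in enumerate(windows):
                    res = anchor_peak_window(w, scan_pwm, cfg.halfwidth, threshold,
                                             cfg.orient_minus_strand)
                    if res is None:
                        continue
                    s, span, strand = res
                    aligned.append(AlignedSequence(s, int(labels[i]),
                                                   core_span=span, core_strand=strand))
                    keep.append(i)
                keep = np.asarray(keep, dtype=int)
                info["dropped_fraction"] = 1.0 - len(keep) / len(windows)
                labels = labels[keep]
                split = split[keep]
                original_scores = self._best_hit_scores(aligned, scan_pwm)

        return self._fit_aligned(aligned, labels, split, seeds, info,
                                 original_scores)

    @staticmethod
    def _best_hit_scores(aligned, scan_pwm) -> np.ndarray:
        from .motifs import scan_scores
        codes = np.stack([s.codes for s in aligned])
        return scan_scores(codes, scan_pwm).max(axis=(-2, -1))

    def _fit_aligned(self, aligned, labels, split, seeds, info,
                     original_scores) -> "DifferentialBindingResults":
        cfg = self.config
        tr = split
        has_dm = not self.skip_anchoring and aligned[0].core_span is not None

        columns, meta, dpwm, class_ppms = [], [], None, None
        if has_dm:
            sites = [dm_mod.extract_core_flank(s, cfg.n_flank) for s in aligned]
            if any(x is None for x in sites):
                keep = np.array([x is not None for x in sites])
                aligned = [s for s, k in zip(aligned, keep) if k]
                labels, split, tr = labels[keep], split[keep], split[keep]
                sites = [x for x in sites if x is not None]
                if original_scores is not None:
                    original_scores = original_scores[keep]
            sites_tr_a = [s for s, t, l in zip(sites, tr, labels) if t and l == 1]
            sites_tr_b = [s for s, t, l in zip(sites, tr, labels) if t and l == 0]
            dpwm = dm_mod.fit_discriminative_pwm(
                sites_tr_a, sites_tr_b, seed=seeds[2], n_flank=cfg.n_flank,
                penalized=True, lambda_rule=cfg.lambda_rule_dm, n_folds=cfg.n_folds)
            dm_col = dm_mod.pwm_site_scores(sites, dpwm.weights)
            columns.append(dm_col)
            a0, b0 = aligned[0].core_span
            meta.append(("DM", "DM", dpwm.pwm.consensus(),
                         a0 - len(aligned[0].seq) // 2,
                         b0 - len(aligned[0].seq) // 2))
            cores = [s.seq[s.core_span[0]:s.core_span[1]] for s in aligned]
            cores_a = [c for c, t, l in zip(cores, tr, labels) if t and l == 1]
            cores_b = [c for c, t, l in zip(cores, tr, labels) if t and l == 0]
            class_ppms = estimate_class_ppms(cores_a, cores_b, pseudocount=0.5)
            masked = [mask_core(s) for s in aligned]
        else:
            masked = aligned
            sites, cores = None, None

        # label-independent pre-computations, shared by the master discovery
        # and every CV fold's re-discovery
        counts_all = None
        if cfg.use_ne:
            counts_all = ne_mod.KmerRegionCounts(masked, n_bins=cfg.ne_bins,
                                                 max_k=cfg.ne_max_k)
        cf_mats = [cf_mod.BinScoreMatrix(masked, pwm, n_bins=cfg.cf_bins)
                   for pwm in self.library]
        dm_values = columns[0] if columns else None
        dm_meta = meta[0] if meta else None
        from .stats import folded_auroc_rows

        cf_lattices = [cf_mod.lattice_region_scores(m.scores, m.bins)
                       for m in cf_mats]
        ne_cache: dict[bytes, list] = {}

        def discover(tmask, whole_cf=False, with_features=False):
            """Feature discovery restricted to `tmask` rows; values for all."""
            cols: dict[str, np.ndarray] = {}
            metas, nef, cff = [], [], []
            if dm_values is not None:
                cols["DM"] = dm_values
                metas.append(dm_meta)
            if counts_all is not None:
                key = tmask.tobytes()  # NE discovery is CF-independent
                if key not in ne_cache:
                    ne_cache[key] = ne_mod.explore_ne_features(
                        None, labels[tmask], n_bins=cfg.ne_bins,
                        max_k=cfg.ne_max_k, min_gain=cfg.ne_min_gain,
                        include_seeds=cfg.ne_include_seeds,
                        counts=_subset_counts(counts_all, tmask))
                nef = ne_cache[key]
                for f in nef:
                    cols[f.name] = counts_all.frequencies(f.kmer, f.region)
                    metas.append((f.name, "NE", f.kmer, f.region.bp_start,
                                  f.region.bp_end))
            for pwm, m, lattice in zip(self.library, cf_mats, cf_lattices):
                if whole_cf:
                    region = Region(0, cfg.cf_bins - 1, m.bins[0].bp_start,
                                    m.bins[-1].bp_end)
                    scores = lattice[region]
                    a = float(folded_auroc_rows(scores[tmask][None, :],
                                                labels[tmask])[0])
                else:
                    regions = list(lattice)
                    aurocs = folded_auroc_rows(
                        np.stack([lattice[r][tmask] for r in regions]),
                        labels[tmask])
                    keys = [(av, r.n_bins, -r.first_bin)
                            for av, r in zip(aurocs, regions)]
                    i = max(range(len(keys)), key=keys.__getitem__)
                    region, a = regions[i], float(aurocs[i])
                    scores = lattice[region]
                feat = cf_mod.CFFeature(pwm.name or "pwm", region, a)
                cff.append(feat)
                cols[feat.name] = scores
                metas.append((feat.name, "CF", feat.pwm_name,
                              region.bp_start, region.bp_end))
            values = pd.DataFrame(cols)
            if with_features:
                return values, metas, nef, cff
            return values

        values, meta, ne_features, cf_features = discover(tr, with_features=True)
        column_meta = pd.DataFrame(meta, columns=["name", "group", "identity",
                                                  "region_start", "region_end"])
        table = FeatureTable(values, labels, split, column_meta)
        gfit = fit_global_nested(table, discover, seed=seeds[3],
                                 rule=cfg.lambda_rule_global,
                                 n_folds=cfg.n_folds)

        # whole-sequence-CF variant: CF columns forced to the lattice top
        whole_fit = whole_table = None
        if self.library:
            wvals, wmeta, _, _ = discover(tr, whole_cf=True, with_features=True)
            whole_table = FeatureTable(
                wvals, labels, split,
                pd.DataFrame(wmeta, columns=["name", "group", "identity",
                                             "region_start", "region_end"]))
            whole_fit = fit_global_nested(
                whole_table, lambda m: discover(m, whole_cf=True),
                seed=seeds[3], rule=cfg.lambda_rule_global, n_folds=cfg.n_folds)

        return DifferentialBindingResults(
            model=self, config=cfg, table=table, global_fit=gfit, dpwm=dpwm,
            class_ppms=class_ppms, ne_features=ne_features,
            cf_features=cf_features, whole_cf_fit=whole_fit,
            whole_cf_table=whole_table, original_scores=original_scores,
            sites=sites, info=info, aligned=aligned)


def _subset_counts(counts: ne_mod.KmerRegionCounts, mask) -> ne_mod.KmerRegionCounts:
    """Training-row view of precomputed k-mer bin counts (no recount)."""
    import copy

    sub = copy.copy(counts)
    sub.counts = {k: v[mask] for k, v in counts.counts.items()}
    sub.valid = {k: v[mask] for k, v in counts.valid.items()}
    return sub


@dataclass
class DifferentialBindingResults:
    """Fitted differential-binding model: estimates, accuracy, reports."""

    model: DifferentialBindingModel
    config: ModelConfig
    table: FeatureTable
    global_fit: FittedModel
    dpwm: dm_mod.DiscriminativePWM | None
    class_ppms: tuple[PPM, PPM] | None
    ne_features: list
    cf_features: list
    whole_cf_fit: FittedModel | None
    whole_cf_table: FeatureTable | None
    original_scores: np.ndarray | None
    sites: list | None
    info: dict
    aligned: list

    # -- accuracy -----------------------------------------------------------

    def _test_auroc(self, fit: FittedModel, table: FeatureTable) -> float:
        te = ~table.train
        return auroc(fit.linear_scores(table.values)[te], table.labels[te])

    @property
    def auroc_test(self) -> float:
        return self._test_auroc(self.global_fit, self.table)

    @property
    def auroc_train(self) -> float:
        trm = self.table.train
        return auroc(self.global_fit.linear_scores(self.table.values)[trm],
                     self.table.labels[trm])

    def ablate(self, group: str) -> float:
        return ablate(self.global_fit, self.table, group)

    def importance_profile(self) -> np.ndarray:
        """AUROC(full) - AUROC(w/o DM, w/o NE, w/o CF) on the test rows."""
        full = self.auroc_test
        return np.array([full - self.ablate(g) for g in GROUPS])

    def single_module_auroc(self, group: str, seed: int = 0) -> float:
        """Test AUROC of a model retrained on one feature group only."""
        mask = self.table.column_meta["group"] == group
        if not mask.any():
            raise ValueError(f"no {group} columns in the table")
        sub = FeatureTable(self.table.values.loc[:, mask.to_numpy()],
                           self.table.labels, self.table.split,
                           self.table.column_meta[mask].reset_index(drop=True))
        fit = fit_global(sub, seed=seed, rule=self.config.lambda_rule_global,
                         n_folds=self.config.n_folds)
        return self._test_auroc(fit, sub)

    def importance(self, n_keep: int | None = None) -> pd.DataFrame:
        return variable_importance(self.global_fit, self.table,
                                   n_keep or self.config.n_keep)

    # -- reports ------------------------------------------------------------

    def radar_record(self) -> dict[str, float]:
        """Named test AUROCs of the model and its alternatives."""
        te = ~self.table.train
        y = self.table.labels[te]
        rec = {"full": self.auroc_test,
               "wo_DM": self.ablate("DM"),
               "wo_NE": self.ablate("NE"),
               "wo_CF": self.ablate("CF")}
        if self.original_scores is not None:
            rec["original_pwm"] = auroc(self.original_scores[te], y)
        if self.dpwm is not None:
            dmcol = self.table.values["DM"].to_numpy()
            rec["dm_only"] = auroc(dmcol[te], y)
            rec["two_ppm"] = self.two_ppm_auroc()
        if self.whole_cf_fit is not None:
            rec["cf_whole_sequence"] = self._test_auroc(self.whole_cf_fit,
                                                        self.whole_cf_table)
        return rec

    def two_ppm_auroc(self) -> float:
        trm = self.table.train
        sites = self.sites
        labels = self.table.labels
        idx_tr, idx_te = np.flatnonzero(trm), np.flatnonzero(~trm)
        cores = [s.seq[s.core_span[0]:s.core_span[1]] for s in self.aligned]
        p1, p2 = self.class_ppms
        return dm_mod.two_ppm_baseline(
            p1, p2, [cores[i] for i in idx_tr], labels[idx_tr],
            [cores[i] for i in idx_te], labels[idx_te],
            self.config.background, self.config.pseudocount)

    def location_record(self, top_n: int | None = None) -> pd.DataFrame:
        """The most important variables with identity, bp region and class."""
        return self.importance(top_n or self.config.top_n)

    def model_record(self) -> str:
        """Canonical JSON of every train-derived quantity (audit surface)."""
        rec = {
            "info": {k: v for k, v in self.info.items()},
            "dm": None if self.dpwm is None else {
                "weights": np.round(self.dpwm.weights, 10).tolist(),
                "intercept": round(self.dpwm.intercept, 10),
                "lambda": self.dpwm.lasso_lambda,
                "n_flank": self.dpwm.n_flank,
            },
            "ne_features": [[f.kmer, f.region.first_bin, f.region.last_bin,
                             round(f.train_auroc, 10)] for f in self.ne_features],
            "cf_features": [[f.pwm_name, f.region.first_bin, f.region.last_bin,
                             round(f.train_auroc, 10)] for f in self.cf_features],
            "global": {
                "columns": self.global_fit.columns,
                "coef": np.round(self.global_fit.coef, 10).tolist(),
                "intercept": round(self.global_fit.intercept, 10),
                "lambda": self.global_fit.lambda_,
                "mean": np.round(self.global_fit.mean, 10).tolist(),
                "scale": np.round(self.global_fit.scale, 10).tolist(),
            },
        }
        return json.dumps(rec, sort_keys=True)

    def run_record(self) -> dict:
        """JSON-serializable run summary (config, seeds, AUROCs, lambdas)."""
        return {
            "config": asdict(self.config),
            "info": self.info,
            "n_train": int(self.table.train.sum()),
            "n_test": int((~self.table.train).sum()),
            "aurocs": self.radar_record(),
            "importance_profile": self.importance_profile().tolist(),
            "global_lambda": self.global_fit.lambda_,
            "global_nonzero": self.global_fit.nonzero,
        }

    def summary(self) -> str:
        rec = self.radar_record()
        lines = ["Differential binding model", "=" * 40,
                 f"sequences: {len(self.table.labels)} "
                 f"(train {int(self.table.train.sum())} / "
                 f"test {int((~self.table.train).sum())})",
                 f"features: {len(self.global_fit.columns)} "
                 f"({self.global_fit.nonzero} selected, "
                 f"lambda={self.global_fit.lambda_:.4g})",
                 "", "Test AUROC by model variant:"]
        for k, v in sorted(rec.items(), key=lambda kv: -kv[1]):
            lines.append(f"  {k:<20s} {v:6.3f}")
        lines.append("")
        lines.append("Importance profile (AUROC loss when ablated):")
        for g, d in zip(GROUPS, self.importance_profile()):
            lines.append(f"  {g:<4s} {d:+.3f}")
        imp = self.importance()
        if len(imp):
            lines.append("")
            lines.append("Top variables (compact-model importance):")
            for _, r in imp.head(10).iterrows():
                lines.append(f"  {int(r['rank']):>2d}. {r['name']:<28s} "
                             f"class{int(r['associated_class'])} "
                             f"dAUROC={r['delta_auroc']:+.3f}")
        return "\n".join(lines)
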