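"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure of a pan-cancer bulk RNA-seq cohort
stratified by telomerase (TERT) expression status:

* several tumor types, each with 4-6 tissue-matched controls;
* a marker gene with bimodal expression — a zero mode (a configurable
  fraction of samples, ~27% by default) and a log-normal positive mode;
* gene modules planted to correlate positively or negatively with the
  marker through a single latent factor (the standardized rank of the
  marker's latent activity), which guarantees the monotone association a
  Spearman screen is designed to detect;
* signed pathways whose member roles are arranged so that "active"
  pathways have positive expected activation (PAL) in marker-positive
  samples;
* negative-binomial count noise (variance = mu + mu^2/k, dispersion k
  shared across genes);
* promoter-mutation labels assigned to a fraction of marker-positive
  samples with deliberately *no* expression effect (a planted null);
* two transposable-element subfamilies (L1HS, L1PA2) elevated in
  marker-negative samples.

Everything is reproducible from the seed, and :func:`truth_eval` scores
pipeline outputs against the planted truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import io as tio
from .errors import ConfigError, DataContractError
from .io import PathwayLibrary


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults give ~200 tumor samples across 5 types with the bimodal marker
    split, module correlation strength and mutation-label fraction matching
    the cohort structure the pipeline targets.
    """

    seed: int = 0
    n_types: int = 5
    samples_per_type: int = 40
    controls_per_type: int = 5
    n_genes: int = 1000
    frac_marker_negative: float = 0.27
    marker_mu: float = 3.0       # log-mean of the positive mode (natural log)
    marker_sigma: float = 1.0    # log-sd of the positive mode
    n_pos_corr: int = 30
    n_neg_corr: int = 30
    corr_strength: float = 0.6   # latent-factor loading (log units per SD)
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (5, 15)
    frac_active_pathways: float = 0.3
    activation_shift: float = 1.0  # log2 member-gene shift in marker-pos samples
    nb_dispersion: float = 10.0
    frac_mut: float = 0.13
    te_effect: float = 3.0       # fold elevation of L1 in marker-neg samples

    def __post_init__(self) -> None:
        for name in ("frac_marker_negative", "frac_active_pathways", "frac_mut"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not (4 <= self.controls_per_type <= 6):
            raise ConfigError("controls_per_type must lie in [4, 6]")
        for name in ("n_types", "samples_per_type", "n_genes", "n_pathways"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.nb_dispersion <= 0 or self.te_effect <= 0 or self.activation_shift <= 0:
            raise ConfigError("nb_dispersion, te_effect and activation_shift must be > 0")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi):
            raise ConfigError("pathway_size_range must satisfy 1 <= lo <= hi")


@dataclass
class GroundTruth:
    """Planted signals: per-gene module membership, per-pathway activity,
    per-sample stratum and mutation label, and the TE effect."""

    genes: pd.DataFrame       # index gene_id: module, direction, loading
    pathways: pd.DataFrame    # index pathway_id: active, direction
    samples: pd.DataFrame     # index sample_id: true_stratum, mutation_status
    te_effect: float
    te_up_in: str = "neg"     # TE subfamilies elevated in marker-negative tumors


@dataclass
class SimResult:
    counts: pd.DataFrame
    samples: pd.DataFrame
    library: PathwayLibrary
    te_counts: pd.DataFrame
    te_subfamily: pd.Series
    tf_list: list[str]
    truth: GroundTruth
    config: SimConfig


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, k: float) -> np.ndarray:
    """Negative binomial draws with variance mu + mu^2/k; exact zeros kept."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        p = k / (k + mean[pos])
        out[pos] = rng.negative_binomial(k, p)
    return out


def simulate_cohort(cfg: SimConfig | None = None) -> SimResult:
    """Generate a full synthetic cohort with recoverable planted structure."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    n_active = int(round(cfg.frac_active_pathways * cfg.n_pathways))
    lo, hi = cfg.pathway_size_range
    active_sizes = rng.integers(lo, hi + 1, size=n_active)
    n_pathway_genes = int(active_sizes.sum())
    n_planted = cfg.n_pos_corr + cfg.n_neg_corr + n_pathway_genes
    if n_planted >= cfg.n_genes:
        raise ConfigError(
            f"planted genes ({n_planted}) must be fewer than n_genes ({cfg.n_genes})"
        )

    marker = "TERT"
    gene_ids = [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]
    pos_genes = gene_ids[: cfg.n_pos_corr]
    neg_genes = gene_ids[cfg.n_pos_corr: cfg.n_pos_corr + cfg.n_neg_corr]
    pw_genes = gene_ids[cfg.n_pos_corr + cfg.n_neg_corr: n_planted]
    null_genes = gene_ids[n_planted:]
    all_genes = [marker] + gene_ids

    # --- samples ---------------------------------------------------------
    types = [f"type{t:02d}" for t in range(1, cfg.n_types + 1)]
    tumor_ids, tumor_types = [], []
    for t in types:
        for i in range(1, cfg.samples_per_type + 1):
            tumor_ids.append(f"T_{t}_{i:03d}")
            tumor_types.append(t)
    control_ids, control_types = [], []
    for t in types:
        for i in range(1, cfg.controls_per_type + 1):
            control_ids.append(f"C_{t}_{i:02d}")
            control_types.append(t)
    n_tumor = len(tumor_ids)

    # --- latent marker activity & strata ---------------------------------
    is_neg = rng.random(n_tumor) < cfg.frac_marker_negative
    t_latent = np.where(
        is_neg, 0.0, rng.lognormal(cfg.marker_mu, cfg.marker_sigma, size=n_tumor)
    )
    z = rankdata(t_latent, method="average")
    z = (z - z.mean()) / z.std()

    # --- per-gene baselines and per-type factors --------------------------
    baseline = rng.lognormal(np.log(100.0), 1.0, size=cfg.n_genes)
    type_factor = rng.lognormal(0.0, 0.3, size=(cfg.n_genes, cfg.n_types))
    type_index = {t: i for i, t in enumerate(types)}

    gene_idx = {g: i for i, g in enumerate(gene_ids)}
    loading = np.zeros(cfg.n_genes)
    for g in pos_genes:
        loading[gene_idx[g]] = cfg.corr_strength
    for g in neg_genes:
        loading[gene_idx[g]] = -cfg.corr_strength

    # --- pathways ---------------------------------------------------------
    pathways: dict[str, dict[str, int]] = {}
    descriptions: dict[str, str] = {}
    pw_active: dict[str, bool] = {}
    role_vec = np.zeros(cfg.n_genes)  # ARR of active-pathway member genes
    cursor = 0
    for p in range(n_active):
        pid = f"PW_active_{p + 1:03d}"
        members = pw_genes[cursor: cursor + int(active_sizes[p])]
        cursor += int(active_sizes[p])
        roles = {g: (1 if rng.random() < 0.7 else -1) for g in members}
        for g, a in roles.items():
            role_vec[gene_idx[g]] = a
        pathways[pid] = roles
        descriptions[pid] = "planted active pathway (up in marker-positive samples)"
        pw_active[pid] = True
    for p in range(cfg.n_pathways - n_active):
        pid = f"PW_null_{p + 1:03d}"
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(null_genes, size=size, replace=False))
        roles = {}
        for g in members:
            u = rng.random()
            roles[g] = 0 if u < 0.1 else (1 if u < 0.55 else -1)
        pathways[pid] = roles
        descriptions[pid] = "planted null pathway"
        pw_active[pid] = False
    library = PathwayLibrary(pathways, descriptions)

    # --- expected counts and noise ---------------------------------------
    log2_shift = cfg.activation_shift * np.log(2.0)
    tumor_mean = np.empty((cfg.n_genes, n_tumor))
    for j in range(n_tumor):
        ti = type_index[tumor_types[j]]
        mu = baseline * type_factor[:, ti] * np.exp(loading * z[j])
        if not is_neg[j]:  # active-pathway member genes shift with their role
            mu = mu * np.exp(role_vec * log2_shift)
        tumor_mean[:, j] = mu
    control_mean = np.empty((cfg.n_genes, len(control_ids)))
    for j, t in enumerate(control_types):
        control_mean[:, j] = baseline * type_factor[:, type_index[t]]

    tumor_counts = _nb_sample(rng, tumor_mean, cfg.nb_dispersion)
    control_counts = _nb_sample(rng, control_mean, cfg.nb_dispersion)
    marker_tumor = _nb_sample(rng, t_latent, cfg.nb_dispersion)
    marker_tumor[is_neg] = 0  # zero mode is exact by construction
    marker_control = np.zeros(len(control_ids), dtype=np.int64)

    counts = pd.DataFrame(
        np.vstack([
            np.concatenate([marker_tumor, marker_control])[None, :],
            np.hstack([tumor_counts, control_counts]),
        ]),
        index=pd.Index(all_genes, name="gene_id"),
        columns=tumor_ids + control_ids,
        dtype=np.int64,
    )

    # --- sample table and mutation labels ---------------------------------
    strata = np.where(is_neg, "neg", "pos")
    mut_status = np.array(["wt"] * n_tumor, dtype=object)
    pos_idx = np.flatnonzero(~is_neg)
    chosen = pos_idx[rng.random(len(pos_idx)) < cfg.frac_mut]
    mut_status[chosen] = rng.choice(["C228T", "C250T"], size=len(chosen), p=[0.7, 0.3])
    samples = pd.DataFrame(
        {
            "tumor_type": tumor_types + control_types,
            "role": ["tumor"] * n_tumor + ["control"] * len(control_ids),
            "tert_stratum": ["unset"] * (n_tumor + len(control_ids)),
            "mutation_status": list(mut_status) + ["unknown"] * len(control_ids),
        },
        index=pd.Index(tumor_ids + control_ids, name="sample_id"),
    )

    # --- transposable elements --------------------------------------------
    te_instances, te_labels, te_base = [], [], []
    for sub in ("L1HS", "L1PA2"):
        for i in range(1, 5):
            te_instances.append(f"{sub}_chr{i}_{1000 * i}")
            te_labels.append(sub)
            te_base.append(rng.lognormal(np.log(200.0), 0.5))
    te_base = np.array(te_base)
    te_mean = np.empty((len(te_instances), n_tumor + len(control_ids)))
    for j in range(n_tumor):
        te_mean[:, j] = te_base * (cfg.te_effect if is_neg[j] else 1.0)
    te_mean[:, n_tumor:] = te_base[:, None]
    te_counts = pd.DataFrame(
        _nb_sample(rng, te_mean, cfg.nb_dispersion),
        index=pd.Index(te_instances, name="instance_id"),
        columns=tumor_ids + control_ids,
    )
    te_subfamily = pd.Series(te_labels, index=te_counts.index, name="subfamily")

    # --- TF list -----------------------------------------------------------
    tf_list = sorted(
        pos_genes[: max(1, cfg.n_pos_corr // 3)]
        + neg_genes[: max(1, cfg.n_neg_corr // 3)]
        + list(rng.choice(null_genes, size=20, replace=False))
    )

    # --- ground truth ------------------------------------------------------
    module = pd.Series("null", index=all_genes, dtype=object)
    module[marker] = "marker"
    module[pos_genes] = "pos_corr"
    module[neg_genes] = "neg_corr"
    module[pw_genes] = "pathway"
    direction = pd.Series(0, index=all_genes, dtype=int)
    direction[pos_genes] = 1
    direction[neg_genes] = -1
    load = pd.Series(0.0, index=all_genes)
    load[gene_ids] = loading
    truth_genes = pd.DataFrame({"module": module, "direction": direction, "loading": load})
    truth_genes.index.name = "gene_id"
    truth_pw = pd.DataFrame(
        {"active": [pw_active[p] for p in pathways], "direction": 1},
        index=pd.Index(list(pathways), name="pathway_id"),
    )
    truth_samples = pd.DataFrame(
        {
            "true_stratum": list(strata) + ["unset"] * len(control_ids),
            "mutation_status": list(mut_status) + ["unknown"] * len(control_ids),
        },
        index=pd.Index(tumor_ids + control_ids, name="sample_id"),
    )
    truth = GroundTruth(truth_genes, truth_pw, truth_samples, cfg.te_effect)

    return SimResult(counts, samples, library, te_counts, te_subfamily, tf_list, truth, cfg)


def write_cohort(result: SimResult, out_dir: str | Path) -> dict[str, Path]:
    """Write every cohort artifact in the package's on-disk dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "pathways": out / "pathways.signed.gmt",
        "te_counts": out / "te_counts.tsv",
        "tf": out / "tf.txt",
        "truth": out / "truth.json",
    }
    tio.write_counts_tsv(result.counts, paths["counts"])
    tio.write_sample_table(result.samples, paths["samples"])
    tio.write_signed_gmt(result.library, paths["pathways"])
    tio.write_te_counts(result.te_counts, result.te_subfamily, paths["te_counts"])
    tio.write_gene_list(result.tf_list, paths["tf"])
    truth_payload = {
        "config": {**asdict(result.config), "pathway_size_range": list(result.config.pathway_size_range)},
        "genes": result.truth.genes.reset_index().to_dict(orient="list"),
        "pathways": result.truth.pathways.reset_index().to_dict(orient="list"),
        "samples": result.truth.samples.reset_index().to_dict(orient="list"),
        "te_effect": result.truth.te_effect,
        "te_up_in": result.truth.te_up_in,
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth_payload, fh, indent=1, sort_keys=True)
    return paths


def truth_eval(
    truth: GroundTruth,
    gene_screen: pd.DataFrame | None = None,
    pal_diff: pd.DataFrame | None = None,
    strata: pd.Series | None = None,
    te_diff: pd.DataFrame | None = None,
) -> dict:
    """Score pipeline outputs against the planted ground truth.

    Reports recall/precision of the correlated-gene screen, recall and
    false-discovery of active-pathway detection, the marker-stratum
    confusion matrix, and whether the TE group effect was recovered with
    the correct direction.
    """
    report: dict = {}
    if gene_screen is not None:
        planted = set(truth.genes.index[truth.genes["module"].isin(["pos_corr", "neg_corr"])])
        nulls = set(truth.genes.index[truth.genes["module"] == "null"])
        tested = set(gene_screen.index)
        if not planted <= tested:
            raise DataContractError("truth_eval: planted genes missing from screen results")
        hits = set(gene_screen.index[gene_screen["passes"]])
        tp = len(hits & planted)
        report["corr_gene_recall"] = tp / len(planted) if planted else float("nan")
        report["corr_gene_precision"] = tp / len(hits) if hits else float("nan")
        report["corr_gene_null_fdp"] = (
            len(hits & nulls) / len(nulls & tested) if nulls & tested else 0.0
        )
        # direction agreement among true positives
        agree = sum(
            1 for g in hits & planted
            if np.sign(gene_screen.loc[g, "rho"]) == truth.genes.loc[g, "direction"]
        )
        report["corr_gene_direction_acc"] = agree / tp if tp else float("nan")
    if pal_diff is not None:
        active = set(truth.pathways.index[truth.pathways["active"]])
        inactive = set(truth.pathways.index[~truth.pathways["active"]])
        tested = set(pal_diff.index)
        hit_col = "passes" if "passes" in pal_diff.columns else "significant"
        hits = set(pal_diff.index[pal_diff[hit_col]])
        report["pathway_recall"] = (
            len(hits & active) / len(active & tested) if active & tested else float("nan")
        )
        report["pathway_null_fdp"] = (
            len(hits & inactive) / len(inactive & tested) if inactive & tested else 0.0
        )
    if strata is not None:
        tumors = truth.samples[truth.samples["true_stratum"] != "unset"]
        missing = set(tumors.index) - set(strata.index)
        if missing:
            raise DataContractError(f"truth_eval: strata missing for {sorted(missing)[:5]}")
        pred = strata.loc[tumors.index]
        confusion = {
            f"stratum_{t}_{p}": int(((tumors["true_stratum"] == t) & (pred == p)).sum())
            for t in ("pos", "neg")
            for p in ("pos", "neg")
        }
        report.update(confusion)
        report["stratum_accuracy"] = (
            confusion["stratum_pos_pos"] + confusion["stratum_neg_neg"]
        ) / len(tumors)
    if te_diff is not None:
        sig = te_diff[te_diff["significant"]]
        report["te_n_significant"] = int(len(sig))
        report["te_direction_correct"] = bool(
            len(sig) > 0 and (sig["up_in"] == "ref").all()
        ) if truth.te_up_in == "neg" else bool(len(sig) > 0 and (sig["up_in"] == "alt").all())
    return report
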