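"""Synthetic paired expression + radiomics studies with known ground truth.

The generator emulates the statistical structure the pipeline consumes:
log2-normal gene intensities with additive class effects (planted DEGs),
per-dataset batch offsets, matched designs with subject intercepts, and a
radiomic table organized as latent cluster prototypes — a subset of which
are sparse linear functions of planted gene modules — plus measurement noise
and constant features. Driver support genes are generated as a co-expressed
module (a shared latent activity factor with signed loadings): differential
genes that drive a common phenotype co-vary in real cohorts, and without
that covariance no per-gene screen could recover an 8-gene support at two
dozen samples. Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, FeatureTable, FEATURE_CLASSES

__all__ = [
    "SyntheticTruth",
    "StudyConfig",
    "StudyData",
    "generate_expression",
    "generate_radiomics",
    "generate_paired_study",
]

_FILTERS = ("original", "wavelet_LLH", "log_sigma_2", "square", "squareroot", "gradient")


@dataclass
class DriverSpec:
    genes: list[str]
    weights: list[float]
    r2_true: float


@dataclass
class SyntheticTruth:
    gene_ids: list[str] = field(default_factory=list)
    deg_ids: list[str] = field(default_factory=list)
    deg_signs: dict = field(default_factory=dict)
    deg_effects: dict = field(default_factory=dict)  # log2 units
    modules: list[dict] = field(default_factory=list)  # genes + signed loadings
    batch_offsets: dict = field(default_factory=dict)  # batch_id -> per-gene vector
    cluster_assignment: dict = field(default_factory=dict)  # feature -> cluster
    driver_map: dict = field(default_factory=dict)  # cluster -> DriverSpec
    constant_feature_ids: list[str] = field(default_factory=list)
    seeds: dict = field(default_factory=dict)

    @property
    def driver_genes(self) -> set[str]:
        out: set[str] = set()
        for spec in self.driver_map.values():
            out.update(spec.genes)
        return out

    @property
    def driver_clusters(self) -> set[int]:
        return set(self.driver_map)


class _GenePool:
    """Shared gene universe: baselines, DEG truth and co-expression modules."""

    def __init__(
        self,
        n_genes: int,
        n_deg: int,
        effect_low: float,
        effect_high: float,
        n_modules: int,
        module_size: int,
        module_rho: float,
        rng: np.random.Generator,
    ):
        if n_deg > n_genes:
            raise ValueError("n_deg cannot exceed n_genes")
        if n_modules * module_size > max(n_deg, 0) and n_modules > 0:
            raise ValueError("modules require n_deg >= n_modules * module_size")
        if not 0.0 <= module_rho < 1.0:
            raise ValueError("module_rho must be in [0, 1)")
        self.gene_ids = [str(10000 + i) for i in range(n_genes)]  # Entrez-like
        self.baseline = rng.normal(7.0, 1.5, size=n_genes)
        deg_idx = rng.choice(n_genes, size=n_deg, replace=False)
        self.deg_idx = np.sort(deg_idx)
        self.effects = rng.uniform(effect_low, effect_high, size=n_deg)
        self.signs = rng.choice([-1, 1], size=n_deg)
        self.module_rho = module_rho
        self.modules: list[dict] = []
        perm = rng.permutation(n_deg)
        for m in range(n_modules):
            members = self.deg_idx[perm[m * module_size : (m + 1) * module_size]]
            loadings = rng.choice([-1.0, 1.0], size=module_size)
            self.modules.append({"idx": members, "loadings": loadings})

    def truth(self) -> SyntheticTruth:
        gid = np.asarray(self.gene_ids)
        deg = gid[self.deg_idx]
        return SyntheticTruth(
            gene_ids=list(self.gene_ids),
            deg_ids=list(deg),
            deg_signs={g: int(s) for g, s in zip(deg, self.signs)},
            deg_effects={g: float(e * s) for g, e, s in zip(deg, self.effects, self.signs)},
            modules=[
                {
                    "genes": list(gid[m["idx"]]),
                    "loadings": [float(l) for l in m["loadings"]],
                    "rho": self.module_rho,
                }
                for m in self.modules
            ],
        )

    def sample_cohort(
        self,
        n_cancer: int,
        n_normal: int,
        noise_sd: float,
        batch_shift_sd: float,
        matched: bool,
        subject_sd: float,
        batch_id: str,
        rng: np.random.Generator,
    ) -> tuple[ExpressionMatrix, np.ndarray]:
        n = n_cancer + n_normal
        if n < 1 or n_cancer < 0 or n_normal < 0:
            raise ValueError("invalid sample counts")
        if matched and n_cancer != n_normal:
            raise ValueError("matched design needs equal cancer and normal counts")
        g = len(self.gene_ids)
        batch = rng.normal(0.0, batch_shift_sd, size=g) if batch_shift_sd > 0 else np.zeros(g)

        values = np.tile((self.baseline + batch)[:, None], (1, n))
        is_cancer = np.zeros(n, dtype=bool)
        is_cancer[:n_cancer] = True
        values[self.deg_idx[:, None], is_cancer[None, :].nonzero()[1]] += (
            self.effects * self.signs
        )[:, None]

        # noise: i.i.d. per gene, except module genes which share a per-sample
        # latent factor (signed loadings) at correlation module_rho
        eps = rng.normal(0.0, 1.0, size=(g, n))
        noise = eps.copy()
        if self.modules:
            u = rng.normal(0.0, 1.0, size=(len(self.modules), n))
            rho = self.module_rho
            for m, mod in enumerate(self.modules):
                idx = mod["idx"]
                noise[idx] = (
                    mod["loadings"][:, None] * np.sqrt(rho) * u[m][None, :]
                    + np.sqrt(1.0 - rho) * eps[idx]
                )
        values += noise_sd * noise

        sample_ids = [f"{batch_id}_C{i+1}" for i in range(n_cancer)] + [
            f"{batch_id}_N{i+1}" for i in range(n_normal)
        ]
        if matched:
            subj = rng.normal(0.0, subject_sd, size=n_cancer)
            values[:, :n_cancer] += subj[None, :]
            values[:, n_cancer:] += subj[None, :]
        classes = ["cancer"] * n_cancer + ["normal"] * n_normal
        return (
            ExpressionMatrix(list(self.gene_ids), sample_ids, values, classes, batch_id),
            batch,
        )


def generate_expression(
    n_genes: int = 1000,
    n_cancer: int = 20,
    n_normal: int = 20,
    n_deg: int = 50,
    effect_low: float = 1.5,
    effect_high: float = 2.5,
    noise_sd: float = 0.5,
    batch_shift_sd: float = 0.0,
    matched: bool = False,
    seed: int = 0,
    batch_id: str = "cohort",
    n_modules: int = 0,
    module_size: int = 8,
    module_rho: float = 0.8,
    subject_sd: float = 0.2,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Two-class log2 expression with planted DEGs and optional batch offset.

    Gene baselines ~ N(7, 1.5^2) log2 units; DEGs receive a class shift of
    magnitude U(effect_low, effect_high) with random sign; per-sample noise
    is N(0, noise_sd^2); `matched=True` pairs each cancer sample with a
    normal sample sharing a subject intercept ~ N(0, subject_sd^2).
    `n_modules > 0` plants co-expressed DEG modules (see module docstring).
    """
    rng = np.random.default_rng(seed)
    pool = _GenePool(
        n_genes, n_deg, effect_low, effect_high, n_modules, module_size, module_rho, rng
    )
    expr, batch = pool.sample_cohort(
        n_cancer, n_normal, noise_sd, batch_shift_sd, matched, subject_sd, batch_id, rng
    )
    truth = pool.truth()
    truth.batch_offsets[batch_id] = batch
    truth.seeds["expression"] = seed
    return expr, truth


def _feature_names(rng: np.random.Generator, count: int, start: int = 0) -> list[str]:
    names = []
    for i in range(start, start + count):
        filt = _FILTERS[i % len(_FILTERS)]
        cls = FEATURE_CLASSES[i % len(FEATURE_CLASSES)]
        names.append(f"{filt}_{cls}_f{i:04d}")
    return names


def generate_radiomics(
    n_samples: int = 24,
    k_true: int = 8,
    members_per_cluster: int = 25,
    n_constant: int = 5,
    noise_sd: float = 0.3,
    anchor_expr: ExpressionMatrix | None = None,
    anchor_truth: SyntheticTruth | None = None,
    n_driver_clusters: int = 0,
    support_size: int = 8,
    r2_true: float = 0.9,
    seed: int = 0,
) -> tuple[FeatureTable, SyntheticTruth]:
    """Radiomic table of K latent cluster prototypes plus noise and constants.

    Each planted cluster j has a per-sample latent prototype z_j; driver
    clusters set z_j to a standardized sparse linear form of planted genes
    (variance fraction r2_true explained by the gene signal, supports taken
    from the anchor truth's modules when present, |weights| ~ U(0.5, 2));
    non-driver prototypes are independent noise. Member features are
    a * z_j + b + N(0, noise_sd^2) with a > 0; constant features are
    appended verbatim.
    """
    rng = np.random.default_rng(seed)
    if n_driver_clusters > k_true:
        raise ValueError("more driver clusters than clusters")
    if anchor_expr is not None:
        sample_ids = list(anchor_expr.sample_ids)
        n_samples = len(sample_ids)
        if anchor_truth is None:
            raise ValueError("anchor_expr requires its matching anchor_truth")
    else:
        sample_ids = [f"S{i+1:03d}" for i in range(n_samples)]
        if n_driver_clusters > 0:
            raise ValueError("driver clusters require an anchoring expression cohort")

    truth = anchor_truth if anchor_truth is not None else SyntheticTruth()
    prototypes = np.empty((k_true, n_samples))
    for j in range(k_true):
        if j < n_driver_clusters:
            if truth.modules and j < len(truth.modules):
                genes = list(truth.modules[j]["genes"])
                signs = np.asarray(truth.modules[j]["loadings"], dtype=float)
                if support_size > len(genes):
                    raise ValueError("support_size exceeds the anchored module size")
                genes = genes[:support_size]
                signs = signs[:support_size]
            else:
                if support_size > len(truth.deg_ids):
                    raise ValueError("support_size exceeds the available DEGs")
                genes = list(rng.choice(truth.deg_ids, size=support_size, replace=False))
                signs = rng.choice([-1.0, 1.0], size=support_size)
            weights = rng.uniform(0.5, 2.0, size=len(genes)) * signs
            X = anchor_expr.subset_genes(genes).values  # genes x samples
            sd = X.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            Z = (X - X.mean(axis=1, keepdims=True)) / sd
            signal = weights @ Z
            signal = (signal - signal.mean()) / signal.std()
            prototypes[j] = np.sqrt(r2_true) * signal + np.sqrt(1 - r2_true) * rng.normal(
                size=n_samples
            )
            truth.driver_map[j] = DriverSpec(genes, [float(w) for w in weights], r2_true)
        else:
            prototypes[j] = rng.normal(size=n_samples)

    n_clustered = k_true * members_per_cluster
    names = _feature_names(rng, n_clustered + n_constant)
    values = np.empty((n_samples, n_clustered + n_constant))
    col = 0
    for j in range(k_true):
        for _ in range(members_per_cluster):
            a = rng.uniform(0.5, 2.0)
            b = rng.normal()
            values[:, col] = a * prototypes[j] + b + rng.normal(0, noise_sd, size=n_samples)
            truth.cluster_assignment[names[col]] = j
            col += 1
    for _ in range(n_constant):
        values[:, col] = rng.normal()
        truth.constant_feature_ids.append(names[col])
        col += 1

    truth.seeds["radiomics"] = seed
    return FeatureTable(sample_ids, names, values), truth


@dataclass
class StudyConfig:
    """Default synthetic study: a paired tumor cohort with radiomics, a
    matched tumor/normal cohort, an independent control cohort and an
    external validation cohort, all sharing one planted DEG truth."""

    n_genes: int = 1000
    n_deg: int = 100
    effect_low: float = 1.5
    effect_high: float = 2.5
    noise_sd: float = 0.5
    batch_shift_sd: float = 0.3
    subject_sd: float = 0.2
    module_rho: float = 0.8
    n_paired: int = 24
    n_tumor_normal: int = 40  # per class, matched
    n_control: int = 40
    n_external: int = 30  # per class, matched
    k_true: int = 15
    members_per_cluster: int = 46
    n_constant: int = 17
    feature_noise_sd: float = 0.3
    n_driver_clusters: int = 5
    support_size: int = 8
    r2_true: float = 0.9


@dataclass
class StudyData:
    cohorts: dict  # name -> ExpressionMatrix
    features: FeatureTable
    truth: SyntheticTruth


def generate_paired_study(config: StudyConfig | None = None, seed: int = 0) -> StudyData:
    """Generate the full four-cohort study plus the paired radiomic table."""
    cfg = config or StudyConfig()
    root = np.random.SeedSequence(seed)
    keys = ["pool", "paired", "tumor_normal", "control", "external", "radiomics"]
    seeds = {k: int(s.generate_state(1)[0] % 2**31) for k, s in zip(keys, root.spawn(len(keys)))}

    rng = np.random.default_rng(seeds["pool"])
    pool = _GenePool(
        cfg.n_genes,
        cfg.n_deg,
        cfg.effect_low,
        cfg.effect_high,
        cfg.n_driver_clusters,
        cfg.support_size,
        cfg.module_rho,
        rng,
    )
    truth = pool.truth()
    truth.seeds.update(seeds)

    def cohort(name, n_c, n_n, matched):
        expr, batch = pool.sample_cohort(
            n_c,
            n_n,
            cfg.noise_sd,
            cfg.batch_shift_sd,
            matched,
            cfg.subject_sd,
            name,
            np.random.default_rng(seeds[name]),
        )
        truth.batch_offsets[name] = batch
        return expr

    cohorts = {
        "paired": cohort("paired", cfg.n_paired, 0, False),
        "tumor_normal": cohort("tumor_normal", cfg.n_tumor_normal, cfg.n_tumor_normal, True),
        "control": cohort("control", 0, cfg.n_control, False),
        "external": cohort("external", cfg.n_external, cfg.n_external, True),
    }
    features, truth = generate_radiomics(
        k_true=cfg.k_true,
        members_per_cluster=cfg.members_per_cluster,
        n_constant=cfg.n_constant,
        noise_sd=cfg.feature_noise_sd,
        anchor_expr=cohorts["paired"],
        anchor_truth=truth,
        n_driver_clusters=cfg.n_driver_clusters,
        support_size=cfg.support_size,
        r2_true=cfg.r2_true,
        seed=seeds["radiomics"],
    )
    return StudyData(cohorts, features, truth)
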