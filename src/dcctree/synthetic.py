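"""Synthetic cohorts from a known DCC-GARCH generative process.

Every subject is one N-dimensional zero-mean series whose per-channel
conditional variances follow GARCH(1,1) and whose conditional correlation
matrix follows the DCC recursion around a long-run matrix Qbar.  The
patient-like group can be given weaker long-run connectivity (off-diagonals
of Qbar shrunk towards zero) and more volatile connectivity (theta1
inflated), and symptom scores can be coupled to a chosen node's mean
connectivity — so every downstream stage of the pipeline has ground truth.

The default long-run matrix is hub-structured (one node more strongly
connected than the rest), mimicking the core-hub organisation of the
default mode network; a uniform Qbar would leave the ranking of connection
strengths — and hence every minimum spanning tree — unchanged under a global
shrinkage of connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from . import _kernels
from .core_io import Cohort, PhenotypeRecord, SubjectTimeSeries

BURN_IN = 200


@dataclass(frozen=True)
class GarchGenParams:
    """omega, alpha, beta of the generating GARCH(1,1); alpha+beta < 1."""

    omega: float = 0.1
    alpha: float = 0.1
    beta: float = 0.8

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.alpha + self.beta >= 1:
            raise ValueError("alpha + beta must be < 1 (covariance stationarity)")

    @property
    def unconditional_variance(self) -> float:
        return self.omega / (1.0 - self.alpha - self.beta)


@dataclass
class DccGenParams:
    """Full parameter set of one subject's generating DCC process."""

    per_node: list[GarchGenParams]
    theta1: float
    theta2: float
    qbar: np.ndarray
    t_len: int
    seed: int

    def __post_init__(self) -> None:
        self.qbar = np.asarray(self.qbar, dtype=float)
        n = len(self.per_node)
        if self.qbar.shape != (n, n):
            raise ValueError("qbar must be N x N for N per-node parameter sets")
        if self.theta1 < 0 or self.theta2 < 0 or self.theta1 + self.theta2 >= 1:
            raise ValueError("need theta1, theta2 >= 0 and theta1 + theta2 < 1")
        if not np.allclose(self.qbar, self.qbar.T):
            raise ValueError("qbar must be symmetric")
        if not np.allclose(np.diag(self.qbar), 1.0):
            raise ValueError("qbar must have unit diagonal")
        if np.linalg.eigvalsh(self.qbar).min() <= 0:
            raise ValueError("qbar must be positive definite")


def hub_qbar(n_nodes: int, hub_corr: float = 0.5, base_corr: float = 0.25,
             hub: int = 0) -> np.ndarray:
    """Long-run correlation matrix with one preferentially-connected hub node."""
    q = np.full((n_nodes, n_nodes), base_corr)
    q[hub, :] = hub_corr
    q[:, hub] = hub_corr
    np.fill_diagonal(q, 1.0)
    if np.linalg.eigvalsh(q).min() <= 0:
        raise ValueError("hub_qbar parameters give a non-positive-definite matrix")
    return q


def factor_qbar(n_nodes: int, lambda_max: float = 0.9,
                lambda_min: float = 0.4) -> np.ndarray:
    """One-factor long-run correlation matrix with graded node loadings.

    q_ij = lambda_i * lambda_j with loadings descending linearly from
    ``lambda_max`` to ``lambda_min``: one shared fluctuation in which every
    node participates to a different degree, so connection strengths form a
    graded continuum (strongly-loading nodes act as hubs) rather than two
    discrete levels.  Positive definite by construction for loadings < 1.
    """
    if not (0 < lambda_min <= lambda_max < 1):
        raise ValueError("need 0 < lambda_min <= lambda_max < 1")
    lam = np.linspace(lambda_max, lambda_min, n_nodes)
    q = np.outer(lam, lam)
    np.fill_diagonal(q, 1.0)
    return q


def scale_offdiagonal(q: np.ndarray, scale: float) -> np.ndarray:
    """Shrink off-diagonal correlations towards zero; preserves definiteness."""
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    return scale * q + (1.0 - scale) * np.eye(q.shape[0])


def simulate_garch_series(params: GarchGenParams, t_len: int, seed: int,
                          burn: int = BURN_IN) -> np.ndarray:
    """One GARCH(1,1) path, recursion initialized at the unconditional variance."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(t_len + burn)
    y = np.empty(t_len + burn)
    s2 = params.unconditional_variance
    y[0] = np.sqrt(s2) * z[0]
    for t in range(1, t_len + burn):
        s2 = params.omega + params.alpha * y[t - 1] ** 2 + params.beta * s2
        y[t] = np.sqrt(s2) * z[t]
    return y[burn:]


def simulate_dcc_process(
    params: DccGenParams,
    distribution: Literal["gaussian", "student"] = "gaussian",
    student_df: float = 5.0,
    burn: int = BURN_IN,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (y, r_true): the N x T series and its true correlation paths.

    Innovations are standard Gaussian by default; the Student-t option
    (standardized to unit variance) provides a heavy-tailed robustness check.
    """
    rng = np.random.default_rng(params.seed)
    n = len(params.per_node)
    total = params.t_len + burn
    if distribution == "gaussian":
        z = rng.standard_normal((n, total))
    elif distribution == "student":
        if student_df <= 2:
            raise ValueError("student_df must exceed 2 for finite variance")
        z = rng.standard_t(student_df, size=(n, total))
        z = z / np.sqrt(student_df / (student_df - 2.0))
    else:
        raise ValueError(f"unknown innovation distribution {distribution!r}")
    omega = np.array([p.omega for p in params.per_node])
    alpha = np.array([p.alpha for p in params.per_node])
    beta = np.array([p.beta for p in params.per_node])
    y, r_true = _kernels.simulate_dcc_paths(
        np.ascontiguousarray(z), np.ascontiguousarray(params.qbar, dtype=float),
        float(params.theta1), float(params.theta2), omega, alpha, beta, burn,
    )
    return y, r_true


@dataclass
class CohortSpec:
    """Study conditions for one simulated two-group cohort.

    ``group_qbar_scale`` shrinks the patient group's long-run off-diagonal
    correlations (lower mean connectivity); ``group_theta_shift`` is added to
    the patient group's theta1 (more volatile connectivity).  ``ados_node``/
    ``ados_coupling`` make patient ADOS scores a linear function of that
    subject's realized time-mean connectivity of the given node (0-based)
    plus Gaussian noise, truncated to non-negative integers.
    """

    n_per_group: tuple[int, int] = (10, 10)
    n_nodes: int = 6
    t_len: int = 300
    garch: GarchGenParams = field(default_factory=GarchGenParams)
    theta1: float = 0.04
    theta2: float = 0.90
    qbar_structure: Literal["factor", "hub"] = "factor"
    lambda_max: float = 0.9
    lambda_min: float = 0.4
    hub_corr: float = 0.5
    base_corr: float = 0.25
    group_qbar_scale: float = 0.5
    group_theta_shift: float = 0.05
    age_mean: float = 17.0
    age_sd: float = 6.0
    iq_mean: float = 110.0
    iq_sd: float = 12.0
    mean_fd_mean: float = 0.08
    mean_fd_sd: float = 0.04
    sites: tuple[str, ...] = ("SITE_A", "SITE_B")
    male_fraction: float = 0.85
    ados_node: int = 0
    ados_coupling: float = 0.0
    ados_intercept: float = 12.0
    ados_noise_sd: float = 2.0
    distribution: Literal["gaussian", "student"] = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        patient_theta1 = self.theta1 + self.group_theta_shift
        if patient_theta1 < 0 or patient_theta1 + self.theta2 >= 1:
            raise ValueError(
                "group_theta_shift makes the patient group violate theta1 + theta2 < 1"
            )
        if not 0 < self.group_qbar_scale <= 1:
            raise ValueError("group_qbar_scale must be in (0, 1]")
        if not 0 <= self.ados_node < self.n_nodes:
            raise ValueError("ados_node out of range")


@dataclass
class GroundTruth:
    """Generating parameters and realized quantities for every subject."""

    spec: CohortSpec
    params: dict[str, DccGenParams] = field(default_factory=dict)
    mean_node_connectivity: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"spec": {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in asdict(self.spec).items()}}
        out["subjects"] = {
            sid: {
                "theta1": p.theta1, "theta2": p.theta2, "seed": p.seed,
                "qbar": p.qbar.tolist(),
                "garch": [asdict(g) for g in p.per_node],
                "mean_node_connectivity": self.mean_node_connectivity.get(sid),
            }
            for sid, p in self.params.items()
        }
        return out


def simulate_dcc_cohort(
    spec: CohortSpec,
) -> tuple[Cohort, dict[str, SubjectTimeSeries], GroundTruth]:
    """Simulate a two-group cohort; group 'ASD' carries the injected effects.

    Fully reproducible from ``spec.seed``: phenotypes, per-subject process
    seeds, innovations and symptom noise all derive from one SeedSequence.
    """
    root = np.random.SeedSequence(spec.seed)
    pheno_rng = np.random.default_rng(root.spawn(1)[0])
    if spec.qbar_structure == "factor":
        qbar_td = factor_qbar(spec.n_nodes, spec.lambda_max, spec.lambda_min)
    else:
        qbar_td = hub_qbar(spec.n_nodes, spec.hub_corr, spec.base_corr)
    qbar_asd = scale_offdiagonal(qbar_td, spec.group_qbar_scale)
    per_node = [spec.garch] * spec.n_nodes

    truth = GroundTruth(spec=spec)
    records: list[PhenotypeRecord] = []
    series: dict[str, SubjectTimeSeries] = {}
    subj_idx = 0
    for group, n_group in zip(("ASD", "TD"), spec.n_per_group):
        for _ in range(n_group):
            subj_idx += 1
            sid = f"sub-{subj_idx:04d}"
            is_patient = group == "ASD"
            params = DccGenParams(
                per_node=list(per_node),
                theta1=spec.theta1 + (spec.group_theta_shift if is_patient else 0.0),
                theta2=spec.theta2,
                qbar=qbar_asd if is_patient else qbar_td,
                t_len=spec.t_len,
                seed=int(root.spawn(1)[0].generate_state(1)[0] % (2**31)),
            )
            y, r_true = simulate_dcc_process(params, distribution=spec.distribution)
            # realized time-mean connectivity of the coupled node (off-diagonal mean)
            node_rows = np.delete(r_true[spec.ados_node], spec.ados_node, axis=0)
            mean_conn = float(node_rows.mean())
            truth.params[sid] = params
            truth.mean_node_connectivity[sid] = mean_conn

            age = float(np.clip(pheno_rng.normal(spec.age_mean, spec.age_sd), 8, 60))
            iq = float(pheno_rng.normal(spec.iq_mean, spec.iq_sd))
            mean_fd = float(abs(pheno_rng.normal(spec.mean_fd_mean, spec.mean_fd_sd)))
            perc_fd = float(np.clip(abs(pheno_rng.normal(5.0, 4.0)), 0, 100))
            sex = "M" if pheno_rng.random() < spec.male_fraction else "F"
            site = spec.sites[subj_idx % len(spec.sites)]
            ados: dict[str, float | None] = {k: None for k in
                                             ("ados_total", "ados_comm",
                                              "ados_social", "ados_stereo_behav")}
            if is_patient:
                base = (spec.ados_intercept + spec.ados_coupling * mean_conn
                        + pheno_rng.normal(0.0, spec.ados_noise_sd))
                total = float(max(0, round(base)))
                # subscales sum approximately to the total
                comm = float(max(0, round(total * 0.35 + pheno_rng.normal(0, 1))))
                social = float(max(0, round(total * 0.5 + pheno_rng.normal(0, 1))))
                stereo = float(max(0, round(total * 0.15 + pheno_rng.normal(0, 0.7))))
                ados = {"ados_total": total, "ados_comm": comm,
                        "ados_social": social, "ados_stereo_behav": stereo}
            records.append(PhenotypeRecord(
                subject_id=sid, group=group, age=age, sex=sex, iq=iq, site=site,
                func_mean_fd=mean_fd, func_perc_fd=perc_fd, **ados,
            ))
            series[sid] = SubjectTimeSeries(subject_id=sid, data=y, demeaned=False)
    return Cohort(records=records), series, truth
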