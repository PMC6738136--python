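"""Ploidy estimation from allele-balance spectra.

For a ploidy-m organism, heterozygous alternate-read fractions cluster near
j/m for carrier multiplicities j = 1..m-1. Each ploidy hypothesis m in
{2, 3, 4} is scored with a Gaussian mixture whose component means are fixed
at those fractions; component standard deviations are fitted by EM. By
default the mixture weights are fixed uniform at 1/(m-1): a ploidy-m
hypothesis asserts that every carrier-multiplicity class occurs in
comparable proportion. Leaving the weights free would let a higher
hypothesis silently reproduce a lower one (e.g. the tetraploid model can
zero its 1/4 and 3/4 components and collapse onto the diploid fit), which
makes likelihood-based model choice between the hypotheses vacuous; pass
``weights="free"`` to get the unconstrained behaviour.

A free 3-component mixture (means, sigmas and weights all free) serves as a
likelihood ceiling, and — augmented with a Uniform(0,1) error component — as
the denoiser: sites whose posterior responsibility is highest for the
uniform component are discarded before fitting.

Hypothesis supports are posterior model probabilities under equal priors
(softmax of total log-likelihood). A ploidy is called only when the best
support exceeds the runner-up by at least the margin threshold (default
0.10); otherwise the call is ambiguous. Genome-wide and
per-contig calls use the same machinery; per-contig results are aggregated
into contig-length-weighted fractions per ploidy level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .variants import AlleleBalanceSite

PLOIDY_HYPOTHESES = (2, 3, 4)
MIN_SITES = 50
MARGIN_THRESHOLD = 0.10
MIN_CONTIG_LEN = 10_000
SIGMA_FLOOR = 1e-3
EM_TOL = 1e-6
EM_MAX_ITER = 500
AMBIGUOUS = "ambiguous"
NO_CALL = "no_call"


@dataclass
class MixtureModel:
    hypothesis: str  # "2" | "3" | "4" | "free" | "free+uniform"
    means: np.ndarray
    sigmas: np.ndarray
    weights: np.ndarray
    loglik: float
    n_sites: int
    n_iter: int
    converged: bool
    uniform_weight: float = 0.0
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class PloidyCall:
    scope: str  # "genome" or a contig id
    n_sites: int
    logliks: dict[int, float]
    supports: dict[int, float]
    call: int | str  # 2/3/4, "ambiguous", or "no_call"
    margin: float


@dataclass
class ContigCall:
    contig: str
    length: int
    call: PloidyCall


@dataclass
class GenomePloidySummary:
    contig_calls: list[ContigCall]
    length_fractions: dict[int, float]  # ploidy -> length-weighted fraction
    margin_pass_fraction: float
    n_contigs_tested: int


def _as_fractions(sites) -> np.ndarray:
    if isinstance(sites, np.ndarray):
        y = sites.astype(float)
    else:
        y = np.array(
            [s.alt_fraction if isinstance(s, AlleleBalanceSite) else float(s) for s in sites]
        )
    if y.size and (y.min() <= 0 or y.max() >= 1):
        raise ValueError("allele-balance fractions must lie strictly in (0,1)")
    return y


def _em(
    y: np.ndarray,
    means: np.ndarray,
    sigmas: np.ndarray,
    weights: np.ndarray,
    free_means: bool,
    free_weights: bool,
    uniform_weight: float | None = None,
    max_iter: int = EM_MAX_ITER,
    tol: float = EM_TOL,
):
    """Generic EM for a Gaussian mixture on (0,1), optionally with a uniform
    error component (density 1). Returns fitted params, loglik path and
    responsibilities. logL is non-decreasing across iterations."""
    n = y.size
    k = means.size
    means = means.astype(float).copy()
    sigmas = np.maximum(sigmas.astype(float).copy(), SIGMA_FLOOR)
    weights = weights.astype(float).copy()
    has_uniform = uniform_weight is not None
    uw = float(uniform_weight) if has_uniform else 0.0
    path: list[float] = []
    resp = None
    yc = y[:, None]
    for it in range(max_iter):
        log_comp = (
            -0.5 * ((yc - means[None, :]) / sigmas[None, :]) ** 2
            - np.log(sigmas[None, :])
            - 0.5 * np.log(2 * np.pi)
        )
        log_w = np.log(np.maximum(weights * (1 - uw if has_uniform else 1.0), 1e-300))
        log_joint = log_comp + log_w[None, :]
        if has_uniform:
            log_joint = np.concatenate(
                [log_joint, np.full((n, 1), np.log(max(uw, 1e-300)))], axis=1
            )
        log_norm = logsumexp(log_joint, axis=1)
        ll = float(log_norm.sum())
        path.append(ll)
        if it > 0 and abs(path[-1] - path[-2]) < tol:
            resp = np.exp(log_joint - log_norm[:, None])
            break
        resp = np.exp(log_joint - log_norm[:, None])
        r = resp[:, :k]
        nk = r.sum(axis=0)
        safe_nk = np.maximum(nk, 1e-12)
        if free_means:
            means = (r * yc).sum(axis=0) / safe_nk
        sigmas = np.sqrt(
            np.maximum(
                (r * (yc - means[None, :]) ** 2).sum(axis=0) / safe_nk,
                SIGMA_FLOOR**2,
            )
        )
        if has_uniform:
            nu = resp[:, k].sum()
            uw = float(np.clip(nu / n, 1e-6, 1 - 1e-6))
            if free_weights:
                weights = safe_nk / max(nk.sum(), 1e-12)
        elif free_weights:
            weights = safe_nk / n
    converged = len(path) < max_iter
    return means, sigmas, weights, uw, path, resp, converged


def fit_fixed_mixture(
    sites,
    ploidy: int,
    min_sites: int = MIN_SITES,
    weights: str = "uniform",
) -> MixtureModel | None:
    """Fit the fixed-mean hypothesis for one ploidy; None if too few sites."""
    if ploidy not in PLOIDY_HYPOTHESES:
        raise ValueError(f"unsupported ploidy hypothesis {ploidy}")
    y = _as_fractions(sites)
    if y.size < min_sites:
        return None
    means = np.array([j / ploidy for j in range(1, ploidy)])
    k = means.size
    w0 = np.full(k, 1.0 / k)
    m, s, w, _, path, _, conv = _em(
        y,
        means,
        np.full(k, 0.1),
        w0,
        free_means=False,
        free_weights=(weights == "free"),
    )
    return MixtureModel(
        hypothesis=str(ploidy),
        means=m,
        sigmas=s,
        weights=w,
        loglik=path[-1],
        n_sites=y.size,
        n_iter=len(path),
        converged=conv,
        loglik_path=np.array(path),
    )


def fit_free_mixture(
    sites,
    min_sites: int = MIN_SITES,
    with_uniform: bool = False,
    multistart: bool = True,
) -> MixtureModel | None:
    """Free 3-component mixture, used as the likelihood ceiling (and, with a
    uniform component, as the denoising model).

    Started from the canonical init {1/4, 1/2, 3/4} and, when ``multistart``
    is on, additionally from each fixed-hypothesis solution expanded to three
    components, so its optimum dominates every fixed model up to EM
    tolerance.
    """
    y = _as_fractions(sites)
    if y.size < min_sites:
        return None
    inits: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = [
        (np.array([0.25, 0.5, 0.75]), np.full(3, 0.1), np.full(3, 1 / 3))
    ]
    for m in PLOIDY_HYPOTHESES if multistart else ():
        fixed = fit_fixed_mixture(y, m, min_sites=min_sites)
        if fixed is None:
            continue
        mu = np.resize(fixed.means, 3).astype(float)
        sg = np.resize(fixed.sigmas, 3).astype(float)
        wt = np.resize(fixed.weights, 3).astype(float)
        wt = wt / wt.sum()
        inits.append((mu, sg, wt))
    best = None
    for mu0, sg0, wt0 in inits:
        uw0 = 0.05 if with_uniform else None
        m, s, w, uw, path, resp, conv = _em(
            y, mu0, sg0, wt0, free_means=True, free_weights=True, uniform_weight=uw0
        )
        if best is None or path[-1] > best[4][-1]:
            best = (m, s, w, uw, path, resp, conv)
    m, s, w, uw, path, resp, conv = best
    return MixtureModel(
        hypothesis="free+uniform" if with_uniform else "free",
        means=m,
        sigmas=s,
        weights=w,
        loglik=path[-1],
        n_sites=y.size,
        n_iter=len(path),
        converged=conv,
        uniform_weight=uw,
        loglik_path=np.array(path),
    )


def denoise(
    sites: list[AlleleBalanceSite] | np.ndarray, min_sites: int = MIN_SITES
) -> tuple[list[AlleleBalanceSite] | np.ndarray, int]:
    """Drop sites best explained by a Uniform(0,1) error component.

    Fits the free mixture plus uniform component and removes every site whose
    posterior responsibility is highest for the uniform component. Returns
    (surviving sites, number removed).
    """
    y = _as_fractions(sites)
    if y.size < min_sites:
        return sites, 0
    model = fit_free_mixture(y, min_sites=min_sites, with_uniform=True, multistart=False)
    log_comp = (
        -0.5 * ((y[:, None] - model.means[None, :]) / model.sigmas[None, :]) ** 2
        - np.log(model.sigmas[None, :])
        - 0.5 * np.log(2 * np.pi)
        + np.log(np.maximum(model.weights * (1 - model.uniform_weight), 1e-300))[None, :]
    )
    log_u = np.full((y.size, 1), np.log(max(model.uniform_weight, 1e-300)))
    keep = np.max(log_comp, axis=1) >= log_u[:, 0]
    removed = int((~keep).sum())
    if isinstance(sites, np.ndarray):
        return y[keep], removed
    return [s for s, k in zip(sites, keep) if k], removed


def call_ploidy(
    sites,
    margin_threshold: float = MARGIN_THRESHOLD,
    min_sites: int = MIN_SITES,
    scope: str = "genome",
    weights: str = "uniform",
) -> PloidyCall:
    """Fit all hypotheses and apply the margin rule.

    Supports are posterior model probabilities under equal priors (softmax of
    the total log-likelihoods). With the weight-constrained hypotheses these
    saturate toward 1 exactly when the data genuinely discriminate the
    hypotheses, and stay split when they do not (e.g. few sites, or free
    weights letting a higher hypothesis collapse onto a lower one). The
    argmax is called only if its support exceeds the runner-up by at least
    ``margin_threshold``.
    """
    y = _as_fractions(sites)
    models = {m: fit_fixed_mixture(y, m, min_sites=min_sites, weights=weights) for m in PLOIDY_HYPOTHESES}
    if any(v is None for v in models.values()):
        return PloidyCall(
            scope=scope, n_sites=int(y.size), logliks={}, supports={}, call=NO_CALL, margin=0.0
        )
    logliks = {m: mod.loglik for m, mod in models.items()}
    best_ll = max(logliks.values())
    raw = {m: float(np.exp(ll - best_ll)) for m, ll in logliks.items()}
    total = sum(raw.values())
    supports = {m: v / total for m, v in raw.items()}
    ranked = sorted(supports.items(), key=lambda kv: kv[1], reverse=True)
    margin = ranked[0][1] - ranked[1][1]
    call: int | str = ranked[0][0] if margin >= margin_threshold else AMBIGUOUS
    return PloidyCall(
        scope=scope,
        n_sites=int(y.size),
        logliks=logliks,
        supports=supports,
        call=call,
        margin=margin,
    )


def contig_ploidy(
    sites: list[AlleleBalanceSite],
    contig_lengths: dict[str, int],
    min_contig_len: int = MIN_CONTIG_LEN,
    min_sites: int = MIN_SITES,
    margin_threshold: float = MARGIN_THRESHOLD,
    denoise_first: bool = True,
) -> GenomePloidySummary:
    """Per-contig calls for contigs longer than ``min_contig_len``, plus
    contig-length-weighted per-ploidy fractions over the called contigs."""
    by_contig: dict[str, list[AlleleBalanceSite]] = {}
    for s in sites:
        by_contig.setdefault(s.contig, []).append(s)

    calls: list[ContigCall] = []
    for contig, length in sorted(contig_lengths.items()):
        if length <= min_contig_len:
            continue
        csites = by_contig.get(contig, [])
        if denoise_first and len(csites) >= min_sites:
            csites, _ = denoise(csites, min_sites=min_sites)
        call = call_ploidy(
            csites, margin_threshold=margin_threshold, min_sites=min_sites, scope=contig
        )
        calls.append(ContigCall(contig=contig, length=length, call=call))

    called = [c for c in calls if isinstance(c.call.call, int)]
    total_len = sum(c.length for c in called)
    length_fractions = {
        m: (sum(c.length for c in called if c.call.call == m) / total_len
            if total_len else 0.0)
        for m in PLOIDY_HYPOTHESES
    }
    tested = [c for c in calls if c.call.call != NO_CALL]
    margin_pass = (
        sum(1 for c in tested if c.call.margin >= margin_threshold) / len(tested)
        if tested
        else 0.0
    )
    return GenomePloidySummary(
        contig_calls=calls,
        length_fractions=length_fractions,
        margin_pass_fraction=margin_pass,
        n_contigs_tested=len(tested),
    )


def write_ploidy_tsv(
    path: str | Path,
    summary: GenomePloidySummary,
    genome_call: PloidyCall | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("scope\tlength\tn_sites\ts2\ts3\ts4\tcall\tmargin\n")
        for cc in summary.contig_calls:
            s = cc.call.supports
            fh.write(
                f"{cc.contig}\t{cc.length}\t{cc.call.n_sites}\t"
                f"{s.get(2, float('nan')):.4f}\t{s.get(3, float('nan')):.4f}\t"
                f"{s.get(4, float('nan')):.4f}\t{cc.call.call}\t{cc.call.margin:.4f}\n"
            )
        if genome_call is not None:
            s = genome_call.supports
            total = sum(contig_lengths.values()) if contig_lengths else 0
            fh.write(
                f"genome\t{total}\t{genome_call.n_sites}\t"
                f"{s.get(2, float('nan')):.4f}\t{s.get(3, float('nan')):.4f}\t"
                f"{s.get(4, float('nan')):.4f}\t{genome_call.call}\t"
                f"{genome_call.margin:.4f}\n"
            )
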