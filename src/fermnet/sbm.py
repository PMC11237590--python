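"""Poisson multiplex stochastic block model, fitted by variational EM.

Each ASV i carries a latent block label z_i ~ Categorical(pi).  Layer l
(one per study) observes, for every unordered pair {i, j} of ASVs present
in that layer, an edge weight A^l_ij ~ Poisson(lam^l_{z_i z_j}) — here the
metric-support count (0..4) of the association.  Block labels are shared
across layers while the rates lam are layer-specific, so blocks collect
ASVs with similar connection patterns across the whole collection of
studies.

Inference is mean-field variational EM: responsibilities tau_iq
approximate the label posterior, the M-step has closed-form updates for pi
and lam, and the E-step is the standard fixed-point update, guarded so the
evidence lower bound (ELBO) never decreases.  The number of blocks is
chosen by the integrated completed likelihood (ICL).

Usage follows the statsmodels convention::

    model = MultiplexSBM.from_multiplex(mplex)
    res = model.fit(Q=3, seed=0)       # -> SBMResults
    res = model.select(range(1, 8), seed=0)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

_EPS_LAM = 1e-10
_EPS_PI = 1e-12


def _as_layer_stack(adjacency) -> np.ndarray:
    A = np.asarray(adjacency, dtype=float)
    if A.ndim == 2:
        A = A[None, :, :]
    if A.ndim != 3 or A.shape[1] != A.shape[2]:
        raise ValueError("adjacency must be an L x N x N stack")
    return A


def _pair_mask(presence: np.ndarray | None, L: int, N: int) -> np.ndarray:
    """Observed-pair masks: both endpoints present, no diagonal."""
    if presence is None:
        mask = np.ones((L, N, N), dtype=float)
    else:
        presence = np.asarray(presence, dtype=bool)
        mask = (presence[:, :, None] & presence[:, None, :]).astype(float)
    idx = np.arange(N)
    mask[:, idx, idx] = 0.0
    return mask


def vem_m_step(A, tau, mask=None) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form M-step.

    pi_q = mean_i tau_iq;  lam^l_qr = sum_{i!=j} tau_iq tau_jr A^l_ij /
    sum_{i!=j} tau_iq tau_jr, both sums restricted to observed pairs.
    Block pairs with no mass get the floor rate 1e-10.
    """
    A = _as_layer_stack(A)
    tau = np.asarray(tau, dtype=float)
    L, N, _ = A.shape
    mask = _pair_mask(None, L, N) if mask is None else np.asarray(mask, dtype=float)
    pi = tau.mean(axis=0)
    lam = np.empty((L, tau.shape[1], tau.shape[1]))
    for l in range(L):
        num = tau.T @ (A[l] * mask[l]) @ tau
        den = tau.T @ mask[l] @ tau
        with np.errstate(divide="ignore", invalid="ignore"):
            rates = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        lam[l] = np.maximum((rates + rates.T) / 2.0, _EPS_LAM)
    return pi, lam


def vem_e_step(A, tau, pi, lam, mask=None, damping: float = 0.0) -> np.ndarray:
    """One fixed-point pass of the mean-field update, log-space normalized.

    log tau'_iq = log pi_q + sum_l sum_{j!=i} sum_r tau_jr
    [A^l_ij log lam^l_qr - lam^l_qr] + const, over observed pairs only.
    ``damping`` in [0, 1) mixes the new tau with the old one.
    """
    A = _as_layer_stack(A)
    tau = np.asarray(tau, dtype=float)
    L, N, _ = A.shape
    mask = _pair_mask(None, L, N) if mask is None else np.asarray(mask, dtype=float)
    log_pi = np.log(np.maximum(pi, _EPS_PI))
    field_ = np.tile(log_pi, (N, 1))
    for l in range(L):
        log_lam = np.log(lam[l])
        field_ += ((A[l] * mask[l]) @ tau) @ log_lam.T
        field_ -= (mask[l] @ tau) @ lam[l].T
    log_tau = field_ - logsumexp(field_, axis=1, keepdims=True)
    new = np.exp(log_tau)
    if damping > 0:
        new = (1 - damping) * new + damping * tau
        new /= new.sum(axis=1, keepdims=True)
    return new


def elbo(A, tau, pi, lam, mask=None) -> float:
    """Evidence lower bound of the Poisson multiplex SBM.

    Entropy of tau + E_q[log p(z)] + E_q[log p(A | z)], each unordered
    observed pair counted once (including its -log A! term, so the bound
    is on the true log-evidence).
    """
    A = _as_layer_stack(A)
    tau = np.asarray(tau, dtype=float)
    L, N, _ = A.shape
    mask = _pair_mask(None, L, N) if mask is None else np.asarray(mask, dtype=float)
    entropy = -float(np.sum(tau * np.log(np.maximum(tau, 1e-300))))
    mixing = float(np.sum(tau @ np.log(np.maximum(pi, _EPS_PI))))
    pair = 0.0
    for l in range(L):
        log_lam = np.log(lam[l])
        Am = A[l] * mask[l]
        pair += 0.5 * float(np.sum((tau.T @ Am @ tau) * log_lam))
        pair -= 0.5 * float(np.sum((tau.T @ mask[l] @ tau) * lam[l]))
        pair -= 0.5 * float(np.sum(mask[l] * gammaln(A[l] + 1.0)))
    return entropy + mixing + pair


def _complete_loglik(A, labels, pi, lam, mask) -> float:
    """Complete-data log-likelihood at hard labels."""
    N = len(labels)
    Q = len(pi)
    hard = np.zeros((N, Q))
    hard[np.arange(N), labels] = 1.0
    value = float(np.sum(np.log(np.maximum(pi, _EPS_PI))[labels]))
    for l in range(A.shape[0]):
        log_lam = np.log(lam[l])
        Am = A[l] * mask[l]
        value += 0.5 * float(np.sum((hard.T @ Am @ hard) * log_lam))
        value -= 0.5 * float(np.sum((hard.T @ mask[l] @ hard) * lam[l]))
        value -= 0.5 * float(np.sum(mask[l] * gammaln(A[l] + 1.0)))
    return value


@dataclass
class SBMResults:
    """Fitted multiplex SBM: posteriors, parameters and diagnostics."""

    model: "MultiplexSBM"
    Q: int
    tau: np.ndarray
    pi: np.ndarray
    lam: np.ndarray
    elbo_trace: np.ndarray
    converged: bool
    n_iter: int
    icl: float = field(default=float("nan"))
    icl_table: dict[int, float] | None = None
    seed: int | None = None

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.tau, axis=1)

    @property
    def elbo(self) -> float:
        return float(self.elbo_trace[-1])

    @property
    def effective_Q(self) -> int:
        return int(len(np.unique(self.labels)))

    def block_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.Q)

    def summary(self) -> str:
        lines = [
            "Poisson multiplex SBM (variational EM)",
            "=" * 46,
            f"nodes:            {self.model.N}",
            f"layers:           {self.model.L}",
            f"blocks (Q):       {self.Q}  (effective: {self.effective_Q})",
            f"ELBO:             {self.elbo:.4f}",
            f"ICL:              {self.icl:.4f}",
            f"converged:        {self.converged}  ({self.n_iter} iterations)",
            "-" * 46,
            "block   size   pi",
        ]
        sizes = self.block_sizes()
        for q in range(self.Q):
            lines.append(f"{q:>5} {sizes[q]:>6}   {self.pi[q]:.4f}")
        if self.icl_table:
            lines.append("-" * 46)
            lines.append("ICL by Q: " + ", ".join(
                f"{q}: {v:.2f}" for q, v in sorted(self.icl_table.items())
            ))
        return "\n".join(lines)


class MultiplexSBM:
    """Poisson multiplex SBM over an aligned collection of networks.

    Parameters
    ----------
    adjacency : (L, N, N) array
        Symmetric non-negative integer edge weights, one layer per study.
    presence : (L, N) bool array, optional
        Node-in-layer flags.  With ``structural_zeros=True`` (default),
        pairs with an absent endpoint are treated as unobserved rather
        than as zero counts: a study that never saw an ASV carries no
        evidence about its associations.
    """

    def __init__(self, adjacency, presence=None, structural_zeros: bool = True,
                 layer_ids=None, node_ids=None):
        self.A = _as_layer_stack(adjacency)
        self.L, self.N, _ = self.A.shape
        for l in range(self.L):
            if not np.allclose(self.A[l], self.A[l].T):
                raise ValueError(f"layer {l}: adjacency not symmetric")
        self.presence = None if presence is None else np.asarray(presence, bool)
        self.structural_zeros = structural_zeros
        self.mask = _pair_mask(
            self.presence if structural_zeros else None, self.L, self.N
        )
        self.layer_ids = list(layer_ids) if layer_ids is not None else [
            str(l) for l in range(self.L)
        ]
        self.node_ids = list(node_ids) if node_ids is not None else None

    @classmethod
    def from_multiplex(cls, mplex, structural_zeros: bool = True) -> "MultiplexSBM":
        adjacency = np.stack([lay.adjacency for lay in mplex.layers])
        presence = np.stack([lay.presence for lay in mplex.layers])
        return cls(
            adjacency, presence=presence, structural_zeros=structural_zeros,
            layer_ids=[lay.study_id for lay in mplex.layers],
            node_ids=list(mplex.node_ids),
        )

    # -- initialization -----------------------------------------------------

    def _spectral_init(self, Q: int, seed: int) -> np.ndarray:
        """KMeans on a Laplacian embedding of the layer-summed adjacency."""
        from sklearn.cluster import KMeans

        total = self.A.sum(axis=0)
        deg = total.sum(axis=1)
        with np.errstate(divide="ignore"):
            d_inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-12)), 0.0)
        sym = d_inv_sqrt[:, None] * total * d_inv_sqrt[None, :]
        vals, vecs = np.linalg.eigh(sym)
        embed = vecs[:, -min(Q, self.N):]
        km = KMeans(n_clusters=Q, n_init=10, random_state=seed % (2**31))
        labels = km.fit_predict(embed)
        return self._harden(labels, Q)

    def _harden(self, labels: np.ndarray, Q: int, strength: float = 0.9) -> np.ndarray:
        tau = np.full((self.N, Q), (1 - strength) / max(Q - 1, 1))
        tau[np.arange(self.N), labels] = strength if Q > 1 else 1.0
        return tau / tau.sum(axis=1, keepdims=True)

    def _random_init(self, Q: int, rng: np.random.Generator) -> np.ndarray:
        tau = rng.dirichlet(np.ones(Q), size=self.N)
        return np.maximum(tau, 1e-6) / np.maximum(tau, 1e-6).sum(1, keepdims=True)

    # -- fitting ------------------------------------------------------------

    def _fit_once(self, Q: int, tau: np.ndarray, tol: float, max_iter: int):
        """Alternate M and guarded E steps; ELBO is monotone by design."""
        pi, lam = vem_m_step(self.A, tau, self.mask)
        current = elbo(self.A, tau, pi, lam, self.mask)
        trace = [current]
        converged = False
        for _ in range(max_iter):
            candidate = vem_e_step(self.A, tau, pi, lam, self.mask)
            cand_elbo = elbo(self.A, candidate, pi, lam, self.mask)
            tries = 0
            while cand_elbo < current - 1e-10 and tries < 25:
                candidate = 0.5 * (candidate + tau)  # damp toward previous tau
                cand_elbo = elbo(self.A, candidate, pi, lam, self.mask)
                tries += 1
            if cand_elbo >= current - 1e-10:
                tau = candidate
            pi, lam = vem_m_step(self.A, tau, self.mask)
            new = elbo(self.A, tau, pi, lam, self.mask)
            trace.append(new)
            if abs(new - current) <= tol * (abs(current) + 1e-12):
                converged = True
                current = new
                break
            current = new
        return tau, pi, lam, np.asarray(trace), converged, len(trace) - 1

    def fit(self, Q: int, n_restarts: int = 10, tol: float = 1e-6,
            max_iter: int = 500, seed: int | None = None) -> SBMResults:
        """Best-ELBO fit over a spectral start plus random restarts."""
        if Q < 1:
            raise ValueError("Q must be >= 1")
        if Q > self.N:
            raise ValueError(f"Q={Q} exceeds the number of nodes N={self.N}")
        rng = np.random.default_rng(seed)
        if Q == 1:
            tau = np.ones((self.N, 1))
            pi, lam = vem_m_step(self.A, tau, self.mask)
            value = elbo(self.A, tau, pi, lam, self.mask)
            res = SBMResults(self, 1, tau, pi, lam, np.array([value]),
                             True, 1, seed=seed)
            res.icl = icl(res)
            return res
        best = None
        for r in range(n_restarts):
            if r == 0:
                try:
                    tau0 = self._spectral_init(Q, int(rng.integers(2**31)))
                except Exception:
                    tau0 = self._random_init(Q, rng)
            else:
                tau0 = self._random_init(Q, rng)
            out = self._fit_once(Q, tau0, tol, max_iter)
            if best is None or out[3][-1] > best[3][-1]:
                best = out
        tau, pi, lam, trace, converged, n_iter = best
        res = SBMResults(self, Q, tau, pi, lam, trace, converged, n_iter, seed=seed)
        res.icl = icl(res)
        return res

    def select(self, Q_range, n_restarts: int = 10, tol: float = 1e-6,
               max_iter: int = 500, seed: int | None = None) -> SBMResults:
        """Fit every Q in ``Q_range`` and return the highest-ICL fit."""
        Q_range = list(Q_range)
        if not Q_range:
            raise ValueError("Q_range must be non-empty")
        rng = np.random.default_rng(seed)
        fits = {}
        for Q in Q_range:
            fits[Q] = self.fit(Q, n_restarts=n_restarts, tol=tol,
                               max_iter=max_iter, seed=int(rng.integers(2**31)))
        table = {Q: f.icl for Q, f in fits.items()}
        best_Q = max(table, key=lambda q: table[q])
        result = fits[best_Q]
        result.icl_table = table
        return result


def icl(results: SBMResults) -> float:
    """Integrated completed likelihood of a fit.

    Complete-data log-likelihood at the MAP labels minus the Daudin-type
    penalty, with the rate-count term multiplied by the number of layers:
    (1/2) L Q(Q+1)/2 log(N(N-1)/2) + ((Q-1)/2) log N.
    """
    model = results.model
    cll = _complete_loglik(model.A, results.labels, results.pi, results.lam,
                           model.mask)
    N, L, Q = model.N, model.L, results.Q
    penalty = 0.5 * L * (Q * (Q + 1) / 2) * np.log(N * (N - 1) / 2)
    penalty += ((Q - 1) / 2) * np.log(N)
    return cll - penalty


def fit_multiplex_sbm(mplex, Q: int, n_restarts: int = 10, tol: float = 1e-6,
                      max_iter: int = 500, seed: int | None = None,
                      structural_zeros: bool = True) -> SBMResults:
    """Convenience wrapper: align -> model -> fit."""
    model = MultiplexSBM.from_multiplex(mplex, structural_zeros=structural_zeros)
    return model.fit(Q, n_restarts=n_restarts, tol=tol, max_iter=max_iter, seed=seed)


def select_model(mplex, Q_range, n_restarts: int = 10, seed: int | None = None,
                 structural_zeros: bool = True, **kwargs) -> SBMResults:
    """Fit each block count in ``Q_range`` and keep the best ICL."""
    model = MultiplexSBM.from_multiplex(mplex, structural_zeros=structural_zeros)
    return model.select(Q_range, n_restarts=n_restarts, seed=seed, **kwargs)
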