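"""Three-state Gaussian-emission hidden Markov model for FRET idealization.

Replaces the interactive HaMMy step of the original workflow: the model is
told to find exactly three states (the 0.0 unbound state plus the two bound
conformations), fit by Baum–Welch EM with scaled forward–backward passes,
and each trajectory is idealized with a Viterbi most-probable path.

Unlike HaMMy's strictly per-trace fits, the default here pools all traces of
a dataset into one fit with shared emission and transition parameters
(short traces under-constrain per-trace fits); a per-trace mode is retained
for fidelity.  Fitting runs on full traces including unbound stretches, so
the lowest-mean state absorbs the unbound baseline.  Fitted states are
always reported sorted by emission mean, and Viterbi ties break toward the
lower state index, so results are deterministic given the inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .fret import FretTrace

__all__ = [
    "GaussianHMM",
    "IdealizedTrace",
    "fit_hmm",
    "idealize",
    "map_states",
    "hmm_to_json",
    "hmm_from_json",
    "INIT_MEANS",
]

#: Published state positions used to seed EM, by labelling scheme.
INIT_MEANS = {"u36": (0.0, 0.25, 0.75), "u63": (0.0, 0.50, 0.90)}

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class IdealizedTrace:
    """Per-frame most-probable state path for one trace."""

    trace_id: str
    state_path: np.ndarray  # labels in {0..n_states-1}, states sorted by mean
    state_means: tuple[float, ...]
    frame_s: float
    mapping: Optional[dict[int, str]] = None  # label -> semantic name

    def __post_init__(self) -> None:
        if len(self.state_path) < 1:
            raise ValueError("idealized path must be non-empty")


def _pack(X: np.ndarray, lengths: Optional[Sequence[int]]) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated observations -> padded (T_max, N) matrix + frame mask."""
    X = np.asarray(X, dtype=float).ravel()
    if X.size == 0:
        raise ValueError("no observations")
    if lengths is None:
        lengths = [X.size]
    lengths = np.asarray(lengths, dtype=int)
    if lengths.sum() != X.size or np.any(lengths < 1):
        raise ValueError("lengths must be positive and sum to len(X)")
    n_seq, t_max = len(lengths), int(lengths.max())
    padded = np.zeros((t_max, n_seq))
    mask = np.zeros((t_max, n_seq), dtype=bool)
    offset = 0
    for n, ln in enumerate(lengths):
        padded[:ln, n] = X[offset : offset + ln]
        mask[:ln, n] = True
        offset += ln
    return padded, mask


class GaussianHMM(BaseEstimator):
    """Gaussian-emission HMM fit by Baum–Welch, decoded by Viterbi.

    Parameters
    ----------
    init_means : starting emission means, one per state (their count sets the
        number of states; three for this assay).
    init_sd : starting emission standard deviation, shared across states.
    self_transition : starting per-frame self-transition probability; the
        remainder is spread uniformly over the other states.
    tol : relative log-likelihood change declaring convergence.
    max_iter : EM iteration cap.
    min_sd : emission sd floor.  With ``on_degenerate="floor"`` (default) a
        collapsing state is clamped to this width and EM continues — the
        right behaviour for genuinely noiseless segments, which would
        otherwise drive a Gaussian singularity.  With
        ``on_degenerate="restart"`` a collapse triggers a re-seeded restart
        (up to ``n_restarts``) and then an error.
    random_state : seeds restart jitter only; a converged first attempt is
        fully deterministic.

    Fitted attributes (states sorted by mean): ``means_``, ``sds_``,
    ``transmat_``, ``startprob_``, ``log_likelihood_``, ``history_``
    (log-likelihood per EM iteration, non-decreasing), ``n_iter_``,
    ``converged_``.
    """

    def __init__(
        self,
        init_means: Sequence[float] = INIT_MEANS["u36"],
        init_sd: float = 0.1,
        self_transition: float = 0.9,
        tol: float = 1e-6,
        max_iter: int = 500,
        min_sd: float = 1e-3,
        n_restarts: int = 3,
        on_degenerate: str = "floor",
        random_state: Optional[int] = None,
    ) -> None:
        self.init_means = init_means
        self.init_sd = init_sd
        self.self_transition = self_transition
        self.tol = tol
        self.max_iter = max_iter
        self.min_sd = min_sd
        self.n_restarts = n_restarts
        self.on_degenerate = on_degenerate
        self.random_state = random_state

    # ------------------------------------------------------------------ EM

    def _emission_pdf(self, x: np.ndarray, mask: np.ndarray,
                      means: np.ndarray, sds: np.ndarray) -> np.ndarray:
        z = (x[..., None] - means) / sds
        b = np.exp(-0.5 * z * z) / (np.sqrt(2.0 * np.pi) * sds)
        b = np.maximum(b, 1e-300)
        b[~mask] = 1.0  # padded frames are emission-neutral
        return b

    def _forward(self, b, mask, startprob, transmat):
        t_max, n_seq, k = b.shape
        alpha = np.empty_like(b)
        scale = np.ones((t_max, n_seq))
        a = startprob[None, :] * b[0]
        scale[0] = a.sum(axis=1)
        alpha[0] = a / scale[0][:, None]
        for t in range(1, t_max):
            a = (alpha[t - 1] @ transmat) * b[t]
            scale[t] = a.sum(axis=1)
            alpha[t] = a / scale[t][:, None]
        ll = float(np.log(scale)[mask].sum())
        return alpha, scale, ll

    def _backward(self, b, scale, transmat):
        t_max, n_seq, k = b.shape
        beta = np.empty_like(b)
        beta[-1] = 1.0
        for t in range(t_max - 2, -1, -1):
            beta[t] = ((b[t + 1] * beta[t + 1]) @ transmat.T) / scale[t + 1][:, None]
        return beta

    def _em_attempt(self, x, mask, init_means, rng):
        k = len(init_means)
        means = np.asarray(init_means, dtype=float)
        sds = np.full(k, float(self.init_sd))
        off = (1.0 - self.self_transition) / (k - 1) if k > 1 else 0.0
        transmat = np.full((k, k), off)
        np.fill_diagonal(transmat, self.self_transition)
        startprob = np.full(k, 1.0 / k)

        history: list[float] = []
        pairmask = mask[1:] & mask[:-1]  # valid (t, t+1) transitions
        converged = False
        for iteration in range(self.max_iter):
            b = self._emission_pdf(x, mask, means, sds)
            alpha, scale, ll = self._forward(b, mask, startprob, transmat)
            if not np.isfinite(ll):
                return None  # numerical collapse; caller restarts
            history.append(ll)
            if len(history) > 1:
                prev = history[-2]
                if (ll - prev) < self.tol * abs(prev):
                    converged = True
                    break
            beta = self._backward(b, scale, transmat)
            post = alpha * beta
            post[~mask] = 0.0

            # tiny floor keeps rare states reachable (no exact-zero
            # probabilities from finite data)
            startprob = post[0].sum(axis=0) + 1e-10
            startprob /= startprob.sum()

            temp = (b[1:] * beta[1:]) / scale[1:][..., None]
            left = alpha[:-1] * pairmask[..., None]
            xi_sum = transmat * np.einsum("tni,tnj->ij", left, temp) + 1e-10
            transmat = xi_sum / xi_sum.sum(axis=1, keepdims=True)

            weight = post.sum(axis=(0, 1))
            means = (post * x[..., None]).sum(axis=(0, 1)) / weight
            var = (post * (x[..., None] - means) ** 2).sum(axis=(0, 1)) / weight
            sds = np.sqrt(var)
            if np.any(sds < self.min_sd):
                if self.on_degenerate == "restart":
                    return None  # degenerate emission; caller restarts
                sds = np.maximum(sds, self.min_sd)

        # Log-likelihood of the final parameters (also the last history entry,
        # keeping the recorded sequence monotone through the final update).
        b = self._emission_pdf(x, mask, means, sds)
        _, _, ll = self._forward(b, mask, startprob, transmat)
        history.append(ll)
        return means, sds, transmat, startprob, history, converged

    def fit(self, X: np.ndarray, lengths: Optional[Sequence[int]] = None) -> "GaussianHMM":
        """Fit to concatenated observations ``X`` split into per-trace
        segments by ``lengths`` (one pooled fit with shared parameters)."""
        if self.on_degenerate not in ("floor", "restart"):
            raise ValueError("on_degenerate must be 'floor' or 'restart'")
        if len(set(np.round(np.asarray(self.init_means, float), 12))) != len(self.init_means):
            raise ValueError("init_means must be distinct")
        x, mask = _pack(X, lengths)
        rng = np.random.default_rng(self.random_state)
        init = np.asarray(self.init_means, dtype=float)
        result = None
        for attempt in range(1 + self.n_restarts):
            result = self._em_attempt(x, mask, init, rng)
            if result is not None:
                break
            init = np.asarray(self.init_means, float) + rng.normal(0.0, 0.05, size=len(self.init_means))
        if result is None:
            raise RuntimeError(
                f"emission variance collapsed below {self.min_sd**2:.1e} in all "
                f"{1 + self.n_restarts} attempts"
            )
        means, sds, transmat, startprob, history, converged = result

        order = np.argsort(means)
        self.means_ = means[order]
        self.sds_ = sds[order]
        self.transmat_ = transmat[np.ix_(order, order)]
        self.startprob_ = startprob[order]
        self.history_ = np.asarray(history)
        self.log_likelihood_ = float(history[-1])
        self.n_iter_ = len(history) - 1
        self.converged_ = converged
        return self

    # ------------------------------------------------------------- decoding

    def _check_fitted(self) -> None:
        if not hasattr(self, "means_"):
            raise RuntimeError("GaussianHMM is not fitted")

    def score(self, X: np.ndarray, lengths: Optional[Sequence[int]] = None) -> float:
        """Total log-likelihood of the observations under the fitted model."""
        self._check_fitted()
        x, mask = _pack(X, lengths)
        b = self._emission_pdf(x, mask, self.means_, self.sds_)
        _, _, ll = self._forward(b, mask, self.startprob_, self.transmat_)
        return ll

    def path_log_likelihood(self, X: np.ndarray, path: np.ndarray) -> float:
        """Joint log-likelihood of one observation sequence and one state
        path (used to check Viterbi optimality)."""
        self._check_fitted()
        x = np.asarray(X, float).ravel()
        path = np.asarray(path, int)
        mu, sd = self.means_[path], self.sds_[path]
        logb = -0.5 * (((x - mu) / sd) ** 2) - np.log(sd) - 0.5 * _LOG_2PI
        ll = float(np.log(self.startprob_[path[0]]) + logb.sum())
        if len(path) > 1:
            ll += float(np.log(self.transmat_[path[:-1], path[1:]]).sum())
        return ll

    def predict(self, X: np.ndarray, lengths: Optional[Sequence[int]] = None) -> np.ndarray:
        """Viterbi decoding; returns the concatenated most-probable path.

        Ties break toward the lower state index at every step.
        """
        self._check_fitted()
        x, mask = _pack(X, lengths)
        t_max, n_seq = x.shape
        k = len(self.means_)
        with np.errstate(divide="ignore"):
            log_a = np.log(self.transmat_)
            log_pi = np.log(self.startprob_)
        z = (x[..., None] - self.means_) / self.sds_
        log_b = -0.5 * z * z - np.log(self.sds_) - 0.5 * _LOG_2PI
        log_b[~mask] = 0.0

        delta_hist = np.empty((t_max, n_seq, k))
        psi = np.zeros((t_max, n_seq, k), dtype=np.int8)
        delta_hist[0] = log_pi[None, :] + log_b[0]
        for t in range(1, t_max):
            cand = delta_hist[t - 1][:, :, None] + log_a[None, :, :]  # (N, from, to)
            psi[t] = np.argmax(cand, axis=1)
            delta_hist[t] = np.max(cand, axis=1) + log_b[t]

        lengths_arr = mask.sum(axis=0)
        out = []
        for n in range(n_seq):
            ln = int(lengths_arr[n])
            path = np.empty(ln, dtype=np.int8)
            path[-1] = np.argmax(delta_hist[ln - 1, n])
            for t in range(ln - 1, 0, -1):
                path[t - 1] = psi[t, n, path[t]]
            out.append(path)
        return np.concatenate(out)


# --------------------------------------------------------------- operations


def fit_hmm(
    frets: Iterable[FretTrace],
    init_means: Optional[Sequence[float]] = None,
    scheme: str = "u36",
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: Optional[int] = None,
    per_trace: bool = False,
    **kwargs,
) -> GaussianHMM | list[GaussianHMM]:
    """Fit the 3-state HMM to a collection of FRET traces.

    Default is one pooled fit across all traces; ``per_trace=True``
    reproduces the literal trace-by-trace protocol and returns one model per
    trace.
    """
    frets = list(frets)
    if not frets:
        raise ValueError("need at least one trace")
    if init_means is None:
        init_means = INIT_MEANS[scheme.lower()]
    make = lambda: GaussianHMM(
        init_means=tuple(init_means), tol=tol, max_iter=max_iter, random_state=seed, **kwargs
    )
    if per_trace:
        return [make().fit(ft.efficiencies) for ft in frets]
    X = np.concatenate([ft.efficiencies for ft in frets])
    lengths = [len(ft) for ft in frets]
    return make().fit(X, lengths)


def idealize(model: GaussianHMM, fret: FretTrace,
             mapping: Optional[dict[int, str]] = None) -> IdealizedTrace:
    """Most-probable (Viterbi) state path for one trace under a fitted model."""
    if len(fret) == 0:
        raise ValueError("cannot idealize an empty trace")
    path = model.predict(fret.efficiencies)
    return IdealizedTrace(
        trace_id=fret.trace_id,
        state_path=path,
        state_means=tuple(float(m) for m in model.means_),
        frame_s=fret.frame_s,
        mapping=mapping,
    )


def map_states(model: GaussianHMM, labelling_scheme: str) -> dict[int, str]:
    """Semantic names for the mean-sorted states of a fitted 3-state model.

    U36 labelling puts the docked conformation at the highest FRET mean and
    the alternative conformation in the middle; U63 labelling inverts the
    two bound states (docked ~0.5 sits below alternative ~0.9).
    """
    model._check_fitted()
    means = np.asarray(model.means_)
    if len(means) != 3:
        raise ValueError("state mapping is defined for 3-state models")
    gaps = np.diff(means)
    if np.any(gaps < 0.1):
        raise ValueError(
            f"fitted means {np.round(means, 3)} are closer than 0.1 FRET; state "
            "identities are ambiguous"
        )
    scheme = labelling_scheme.lower()
    if scheme == "u36":
        return {0: "unbound", 1: "alternative", 2: "docked"}
    if scheme == "u63":
        return {0: "unbound", 1: "docked", 2: "alternative"}
    raise ValueError("labelling_scheme must be 'u36' or 'u63'")


def hmm_to_json(model: GaussianHMM) -> str:
    model._check_fitted()
    return json.dumps(
        {
            "means": list(map(float, model.means_)),
            "sds": list(map(float, model.sds_)),
            "transmat": np.asarray(model.transmat_).tolist(),
            "startprob": list(map(float, model.startprob_)),
            "log_likelihood": model.log_likelihood_,
            "n_iter": model.n_iter_,
            "converged": bool(model.converged_),
        },
        indent=2,
    )


def hmm_from_json(doc: str) -> GaussianHMM:
    data = json.loads(doc)
    model = GaussianHMM(init_means=tuple(data["means"]))
    model.means_ = np.asarray(data["means"])
    model.sds_ = np.asarray(data["sds"])
    model.transmat_ = np.asarray(data["transmat"])
    model.startprob_ = np.asarray(data["startprob"])
    model.log_likelihood_ = data["log_likelihood"]
    model.n_iter_ = data["n_iter"]
    model.converged_ = data["converged"]
    model.history_ = np.asarray([data["log_likelihood"]])
    return model
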