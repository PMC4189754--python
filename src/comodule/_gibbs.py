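"""Numba kernel for collapsed Gibbs sampling of the topic model.

Kept separate from the public API so the heavy dependency surface stays in
one place.  All state is dense int64/float64; token arrays come from the
corpus with a count ``c`` contributing ``c`` token instances.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sample_discrete(p: np.ndarray, total: float) -> int:
    # inverse-CDF draw over unnormalized weights
    r = np.random.random() * total
    acc = 0.0
    for t in range(p.shape[0]):
        acc += p[t]
        if r < acc:
            return t
    return p.shape[0] - 1


@njit(cache=True)
def gibbs_sample(
    doc_ids: np.ndarray,
    word_ids: np.ndarray,
    n_docs: int,
    n_words: int,
    n_topics: int,
    alpha: float,
    beta: float,
    burn_in: int,
    n_samples: int,
    sample_lag: int,
    seed: int,
):
    """Run collapsed Gibbs sampling; return averaged (phi, theta).

    The full conditional for token i in document d with word w is
    proportional to (n_wt + beta) / (n_t + V*beta) * (n_dt + alpha);
    phi and theta are posterior-mean estimates computed per collected
    sample and averaged over samples.
    """
    np.random.seed(seed)
    n_tokens = doc_ids.shape[0]

    nwt = np.zeros((n_words, n_topics), dtype=np.int64)
    ndt = np.zeros((n_docs, n_topics), dtype=np.int64)
    nt = np.zeros(n_topics, dtype=np.int64)
    nd = np.zeros(n_docs, dtype=np.int64)
    z = np.empty(n_tokens, dtype=np.int64)

    for i in range(n_tokens):
        t = np.random.randint(0, n_topics)
        z[i] = t
        nwt[word_ids[i], t] += 1
        ndt[doc_ids[i], t] += 1
        nt[t] += 1
        nd[doc_ids[i]] += 1

    phi_acc = np.zeros((n_topics, n_words), dtype=np.float64)
    theta_acc = np.zeros((n_docs, n_topics), dtype=np.float64)
    p = np.empty(n_topics, dtype=np.float64)
    vbeta = n_words * beta

    total_sweeps = burn_in + n_samples * sample_lag
    collected = 0
    for sweep in range(total_sweeps):
        for i in range(n_tokens):
            w = word_ids[i]
            d = doc_ids[i]
            t_old = z[i]
            nwt[w, t_old] -= 1
            ndt[d, t_old] -= 1
            nt[t_old] -= 1
            total = 0.0
            for t in range(n_topics):
                p[t] = (nwt[w, t] + beta) / (nt[t] + vbeta) * (ndt[d, t] + alpha)
                total += p[t]
            t_new = _sample_discrete(p, total)
            z[i] = t_new
            nwt[w, t_new] += 1
            ndt[d, t_new] += 1
            nt[t_new] += 1
        if sweep >= burn_in and (sweep - burn_in + 1) % sample_lag == 0:
            collected += 1
            for t in range(n_topics):
                denom = nt[t] + vbeta
                for w in range(n_words):
                    phi_acc[t, w] += (nwt[w, t] + beta) / denom
            for d in range(n_docs):
                denom = nd[d] + n_topics * alpha
                for t in range(n_topics):
                    theta_acc[d, t] += (ndt[d, t] + alpha) / denom

    phi_acc /= collected
    theta_acc /= collected
    return phi_acc, theta_acc
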