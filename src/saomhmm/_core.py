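"""Numba kernels for SAOM micro-step dynamics, sample-path likelihoods and
the Metropolis-Hastings sampler over augmenting sample paths.

All kernels operate on plain ``int8`` adjacency matrices and a compiled
effect representation: an integer code per effect plus per-effect actor
covariate vectors (``acov``, shape ``(p, n)``) and centered dyadic
covariate matrices (``dcov``, shape ``(p, n, n)``).  Randomness is drawn
exclusively through a ``numpy.random.Generator`` passed in by the caller,
using only ``gen.random()`` so that streams are reproducible across numba
versions.
"""

import math

import numpy as np
from numba import njit

# Effect codes (must match effects.EFFECT_CODES)
OUTDEGREE = 0
RECIPROCITY = 1
TRANSITIVE_TRIADS = 2
DIST2 = 3
COVARIATE_EGO = 4
COVARIATE_ALTER = 5
DYADIC_COVARIATE = 6


@njit(cache=False)
def actor_stat(u, i, code, av, dv, directed):
    """Statistic of a single effect from actor ``i``'s perspective.

    ``av``: actor covariate vector for this effect, ``dv``: centered
    dyadic covariate matrix.  Unused covariates are all-zero arrays.
    """
    n = u.shape[0]
    s = 0.0
    if code == OUTDEGREE:
        for j in range(n):
            s += u[i, j]
    elif code == RECIPROCITY:
        for j in range(n):
            s += u[i, j] * u[j, i]
    elif code == TRANSITIVE_TRIADS:
        # sum over ordered pairs (j, h): i->j, i->h, j->h
        for j in range(n):
            if u[i, j]:
                for h in range(n):
                    if u[i, h] and u[j, h]:
                        s += 1.0
    elif code == DIST2:
        # number of j != i with no direct tie but reachable via some h
        for j in range(n):
            if j != i and u[i, j] == 0:
                for h in range(n):
                    if u[i, h] and u[h, j]:
                        s += 1.0
                        break
    elif code == COVARIATE_EGO:
        for j in range(n):
            s += u[i, j]
        s *= av[i]
    elif code == COVARIATE_ALTER:
        for j in range(n):
            s += u[i, j] * av[j]
    else:  # DYADIC_COVARIATE
        for j in range(n):
            s += u[i, j] * dv[i, j]
    return s


@njit(cache=False)
def total_stats(u, codes, acov, dcov, directed, out):
    """Per-effect statistic totals over all actors (MoM targets)."""
    p = codes.shape[0]
    n = u.shape[0]
    for e in range(p):
        t = 0.0
        for i in range(n):
            t += actor_stat(u, i, codes[e], acov[e], dcov[e], directed)
        out[e] = t


@njit(cache=False)
def delta_stats(u, i, codes, acov, dcov, directed, out):
    """Change statistics for actor ``i``: ``out[j, e]`` is the change in
    effect ``e``'s statistic when the tie toward ``j`` is toggled (the
    unordered pair {i, j} for undirected networks).  Row ``i`` stays zero
    and encodes the "no change" alternative.
    """
    n = u.shape[0]
    p = codes.shape[0]
    for j in range(n):
        for e in range(p):
            out[j, e] = 0.0
    # current dist2 statistic, if needed (recomputed per toggle)
    for e in range(p):
        if codes[e] == DIST2:
            cur = actor_stat(u, i, DIST2, acov[e], dcov[e], directed)
            for j in range(n):
                if j == i:
                    continue
                u[i, j] = 1 - u[i, j]
                if not directed:
                    u[j, i] = u[i, j]
                out[j, e] = actor_stat(u, i, DIST2, acov[e], dcov[e], directed) - cur
                u[i, j] = 1 - u[i, j]
                if not directed:
                    u[j, i] = u[i, j]
    for j in range(n):
        if j == i:
            continue
        sign = 1.0 - 2.0 * u[i, j]
        for e in range(p):
            c = codes[e]
            if c == OUTDEGREE:
                out[j, e] = sign
            elif c == RECIPROCITY:
                out[j, e] = sign * u[j, i]
            elif c == TRANSITIVE_TRIADS:
                s = 0.0
                if directed:
                    for h in range(n):
                        s += u[i, h] * u[j, h] + u[i, h] * u[h, j]
                else:
                    for h in range(n):
                        s += 2.0 * u[i, h] * u[j, h]
                out[j, e] = sign * s
            elif c == COVARIATE_EGO:
                out[j, e] = sign * acov[e, i]
            elif c == COVARIATE_ALTER:
                out[j, e] = sign * acov[e, j]
            elif c == DYADIC_COVARIATE:
                out[j, e] = sign * dcov[e, i, j]
            # DIST2 handled above
    return out


@njit(cache=False)
def choice_probs(u, i, phi, codes, acov, dcov, directed, dst, probs):
    """Multinomial-logit choice probabilities over the n alternatives of
    actor ``i`` (entry ``j == i`` is the stay alternative).  Evaluated via
    change statistics with max-shift (log-sum-exp) stabilization.
    """
    n = u.shape[0]
    p = phi.shape[0]
    delta_stats(u, i, codes, acov, dcov, directed, dst)
    mx = 0.0  # stay logit is exactly 0
    for j in range(n):
        v = 0.0
        for e in range(p):
            v += phi[e] * dst[j, e]
        probs[j] = v
        if v > mx:
            mx = v
    s = 0.0
    for j in range(n):
        probs[j] = math.exp(probs[j] - mx)
        s += probs[j]
    for j in range(n):
        probs[j] /= s


@njit(cache=False)
def _draw_index(probs, r):
    n = probs.shape[0]
    acc = 0.0
    for k in range(n):
        acc += probs[k]
        if r < acc:
            return k
    return n - 1


@njit(cache=False)
def evolve_period(u, phi, rate, duration, codes, acov, dcov, directed, gen, dst, probs):
    """Evolve ``u`` in place over one period; no path recording."""
    n = u.shape[0]
    lam = n * rate
    if lam <= 0.0 or duration <= 0.0:
        return 0
    t = 0.0
    cnt = 0
    while True:
        t += -math.log(1.0 - gen.random()) / lam
        if t > duration:
            break
        i = int(gen.random() * n)
        if i >= n:
            i = n - 1
        choice_probs(u, i, phi, codes, acov, dcov, directed, dst, probs)
        j = _draw_index(probs, gen.random())
        cnt += 1
        if j != i:
            u[i, j] = 1 - u[i, j]
            if not directed:
                u[j, i] = u[i, j]
    return cnt


@njit(cache=False)
def simulate_period_path(u, phi, rate, duration, codes, acov, dcov, directed, gen):
    """Evolve ``u`` in place and record the full micro-step path.

    Returns ``(steps, times)`` where ``steps[r] = (actor, target)`` with
    target == actor encoding a no-change opportunity.
    """
    n = u.shape[0]
    p = codes.shape[0]
    lam = n * rate
    mean = lam * duration
    cap = int(mean + 10.0 * math.sqrt(mean + 1.0)) + 16
    steps = np.empty((cap, 2), np.int64)
    times = np.empty(cap, np.float64)
    dst = np.empty((n, p), np.float64)
    probs = np.empty(n, np.float64)
    if lam <= 0.0 or duration <= 0.0:
        return steps[:0], times[:0]
    t = 0.0
    R = 0
    while True:
        t += -math.log(1.0 - gen.random()) / lam
        if t > duration:
            break
        if R >= cap:
            ncap = cap * 2
            ns = np.empty((ncap, 2), np.int64)
            nt = np.empty(ncap, np.float64)
            ns[:cap] = steps
            nt[:cap] = times
            steps = ns
            times = nt
            cap = ncap
        i = int(gen.random() * n)
        if i >= n:
            i = n - 1
        choice_probs(u, i, phi, codes, acov, dcov, directed, dst, probs)
        j = _draw_index(probs, gen.random())
        steps[R, 0] = i
        steps[R, 1] = j
        times[R] = t
        R += 1
        if j != i:
            u[i, j] = 1 - u[i, j]
            if not directed:
                u[j, i] = u[i, j]
    return steps[:R].copy(), times[:R].copy()


@njit(cache=False)
def propagate_particles(parents, idx, phi, rate, duration, codes, acov, dcov,
                        directed, gen, out):
    """SAOM one-period evolution of ``parents[idx[k]]`` into ``out[k]``."""
    K = idx.shape[0]
    n = parents.shape[1]
    p = codes.shape[0]
    dst = np.empty((n, p), np.float64)
    probs = np.empty(n, np.float64)
    for k in range(K):
        out[k] = parents[idx[k]]
        evolve_period(out[k], phi, rate, duration, codes, acov, dcov,
                      directed, gen, dst, probs)


@njit(cache=False)
def path_logprob_score(u0, steps, phi, rate, duration, codes, acov, dcov,
                       directed, compute_score, score):
    """Log-probability of a recorded sample path and (optionally) its
    score.  ``score[0]`` is d/d(log rate); ``score[1:]`` is d/d(phi).

    The path probability is the product of the Poisson factor for the
    number of opportunities, the uniform actor-selection factors 1/n and
    the multinomial-logit choice factors, with event times integrated out.
    """
    n = u0.shape[0]
    p = phi.shape[0]
    info = np.zeros((1 + p, 1 + p), np.float64)
    return path_logprob_score_info(u0, steps, phi, rate, duration, codes,
                                   acov, dcov, directed, compute_score,
                                   score, info)


@njit(cache=False)
def path_logprob_score_info(u0, steps, phi, rate, duration, codes, acov,
                            dcov, directed, compute_score, score, info):
    """As :func:`path_logprob_score`, additionally accumulating the
    complete-data information (negative Hessian of the path
    log-likelihood in (log rate, phi)) into ``info``.
    """
    n = u0.shape[0]
    p = phi.shape[0]
    R = steps.shape[0]
    lam = n * rate
    lamdt = lam * duration
    lp = -lamdt
    if R > 0:
        lp += R * math.log(lamdt) - math.lgamma(R + 1.0)
    for e in range(p + 1):
        score[e] = 0.0
        for f in range(p + 1):
            info[e, f] = 0.0
    score[0] = R - lamdt  # d/d log(rate)
    info[0, 0] = lamdt    # -d2/d log(rate)2
    u = u0.copy()
    dst = np.empty((n, p), np.float64)
    probs = np.empty(n, np.float64)
    mean_d = np.empty(p, np.float64)
    logn = math.log(float(n))
    for r in range(R):
        i = steps[r, 0]
        j = steps[r, 1]
        choice_probs(u, i, phi, codes, acov, dcov, directed, dst, probs)
        lp += math.log(probs[j]) - logn
        if compute_score:
            for e in range(p):
                m = 0.0
                for k in range(n):
                    m += probs[k] * dst[k, e]
                mean_d[e] = m
                score[1 + e] += dst[j, e] - m
            # per-step multinomial information: cov of change statistics
            for e in range(p):
                for f in range(e, p):
                    c = 0.0
                    for k in range(n):
                        c += probs[k] * dst[k, e] * dst[k, f]
                    c -= mean_d[e] * mean_d[f]
                    info[1 + e, 1 + f] += c
                    if f != e:
                        info[1 + f, 1 + e] += c
        if j != i:
            u[i, j] = 1 - u[i, j]
            if not directed:
                u[j, i] = u[i, j]
    return lp


@njit(cache=False)
def _step_logp(state, i, j, phi, codes, acov, dcov, directed, dst, probs):
    choice_probs(state, i, phi, codes, acov, dcov, directed, dst, probs)
    return math.log(probs[j])


@njit(cache=False)
def _count_adj_pairs(steps, R):
    """Adjacent identical non-stay step pairs (a toggle and its undo)."""
    c = 0
    for r in range(R - 1):
        if (steps[r, 0] != steps[r, 1] and steps[r, 0] == steps[r + 1, 0]
                and steps[r, 1] == steps[r + 1, 1]):
            c += 1
    return c


@njit(cache=False)
def _count_stays(steps, R):
    c = 0
    for r in range(R):
        if steps[r, 0] == steps[r, 1]:
            c += 1
    return c


@njit(cache=False)
def _count_toggles(steps, R):
    c = 0
    for r in range(R):
        if steps[r, 0] != steps[r, 1]:
            c += 1
    return c


@njit(cache=False)
def mh_path_update(u0, steps_in, phi, rate, duration, codes, acov, dcov,
                   directed, n_props, gen):
    """Metropolis-Hastings sweep over sample paths with both endpoints
    fixed.  Moves: insert/delete an adjacent canceling toggle pair,
    permute two adjacent steps, insert/delete a stay step, and (for
    undirected networks) flip which endpoint of a pair acts.

    Returns ``(steps, n_accept)``; the path's net effect on ``u0`` is
    preserved by construction.
    """
    n = u0.shape[0]
    p = phi.shape[0]
    R = steps_in.shape[0]
    lam = n * rate
    lamdt = lam * duration
    if lamdt <= 0.0:
        return steps_in.copy(), 0
    llamdt = math.log(lamdt)
    logn = math.log(float(n))
    lognd = math.log(float(n * (n - 1)))

    cap = R + 2 * n_props + 8
    steps = np.empty((cap, 2), np.int64)
    steps[:R] = steps_in[:R]
    states = np.empty((cap + 1, n, n), np.int8)
    logp = np.empty(cap, np.float64)
    dst = np.empty((n, p), np.float64)
    probs = np.empty(n, np.float64)

    states[0] = u0
    for r in range(R):
        i = steps[r, 0]
        j = steps[r, 1]
        logp[r] = _step_logp(states[r], i, j, phi, codes, acov, dcov,
                             directed, dst, probs)
        states[r + 1] = states[r]
        if i != j:
            states[r + 1, i, j] = 1 - states[r + 1, i, j]
            if not directed:
                states[r + 1, j, i] = states[r + 1, i, j]

    # move probabilities: [ins pair, del pair, swap, ins stay, del stay, flip]
    pm = np.empty(6, np.float64)
    if directed:
        pm[0] = 0.28; pm[1] = 0.28; pm[2] = 0.24; pm[3] = 0.10; pm[4] = 0.10; pm[5] = 0.0
    else:
        pm[0] = 0.26; pm[1] = 0.26; pm[2] = 0.18; pm[3] = 0.10; pm[4] = 0.10; pm[5] = 0.10
    cm = np.cumsum(pm)

    n_acc = 0
    for _ in range(n_props):
        rmv = gen.random()
        mv = 0
        while mv < 5 and rmv > cm[mv]:
            mv += 1

        if mv == 0:
            # insert adjacent canceling pair of dyad (i,j) before position r
            r = int(gen.random() * (R + 1))
            if r > R:
                r = R
            i = int(gen.random() * n)
            if i >= n:
                i = n - 1
            j = int(gen.random() * (n - 1))
            if j >= n - 1:
                j = n - 2
            if j >= i:
                j += 1
            lp1 = _step_logp(states[r], i, j, phi, codes, acov, dcov,
                             directed, dst, probs)
            mid = states[r].copy()
            mid[i, j] = 1 - mid[i, j]
            if not directed:
                mid[j, i] = mid[i, j]
            lp2 = _step_logp(mid, i, j, phi, codes, acov, dcov, directed,
                             dst, probs)
            dlogf = (2.0 * llamdt - math.log(R + 1.0) - math.log(R + 2.0)
                     - 2.0 * logn + lp1 + lp2)
            # count adjacent pairs in the candidate path
            npairs_new = _count_adj_pairs(steps, R)
            npairs_new += 1  # the inserted pair itself
            if r >= 1 and steps[r - 1, 0] == i and steps[r - 1, 1] == j and i != j:
                npairs_new += 1
            if r < R and steps[r, 0] == i and steps[r, 1] == j and i != j:
                npairs_new += 1
            # the insertion can also break an existing adjacency (r-1, r)
            if (r >= 1 and r < R and steps[r - 1, 0] != steps[r - 1, 1]
                    and steps[r - 1, 0] == steps[r, 0]
                    and steps[r - 1, 1] == steps[r, 1]):
                npairs_new -= 1
            lq_fwd = math.log(pm[0]) - math.log(R + 1.0) - lognd
            lq_rev = math.log(pm[1]) - math.log(float(npairs_new))
            if math.log(1.0 - gen.random()) < dlogf + lq_rev - lq_fwd:
                # shift and insert
                for t in range(R - 1, r - 1, -1):
                    steps[t + 2] = steps[t]
                    logp[t + 2] = logp[t]
                for t in range(R, r - 1, -1):
                    states[t + 2] = states[t]
                steps[r, 0] = i; steps[r, 1] = j
                steps[r + 1, 0] = i; steps[r + 1, 1] = j
                logp[r] = lp1
                logp[r + 1] = lp2
                states[r + 1] = mid
                R += 2
                n_acc += 1

        elif mv == 1:
            npairs = _count_adj_pairs(steps, R)
            if npairs == 0:
                continue
            k = int(gen.random() * npairs)
            if k >= npairs:
                k = npairs - 1
            r = -1
            c = -1
            for t in range(R - 1):
                if (steps[t, 0] != steps[t, 1] and steps[t, 0] == steps[t + 1, 0]
                        and steps[t, 1] == steps[t + 1, 1]):
                    c += 1
                    if c == k:
                        r = t
                        break
            dlogf = (-2.0 * llamdt + math.log(float(R)) + math.log(R - 1.0)
                     + 2.0 * logn - logp[r] - logp[r + 1])
            lq_fwd = math.log(pm[1]) - math.log(float(npairs))
            lq_rev = math.log(pm[0]) - math.log(R - 1.0) - lognd
            if math.log(1.0 - gen.random()) < dlogf + lq_rev - lq_fwd:
                for t in range(r, R - 2):
                    steps[t] = steps[t + 2]
                    logp[t] = logp[t + 2]
                for t in range(r + 1, R - 1):
                    states[t] = states[t + 2]
                R -= 2
                n_acc += 1

        elif mv == 2:
            if R < 2:
                continue
            r = int(gen.random() * (R - 1))
            if r >= R - 1:
                r = R - 2
            i1, j1 = steps[r, 0], steps[r, 1]
            i2, j2 = steps[r + 1, 0], steps[r + 1, 1]
            if i1 == i2 and j1 == j2:
                continue  # identical steps: swap is a no-op
            mid = states[r].copy()
            if i2 != j2:
                mid[i2, j2] = 1 - mid[i2, j2]
                if not directed:
                    mid[j2, i2] = mid[i2, j2]
            lp1 = _step_logp(states[r], i2, j2, phi, codes, acov, dcov,
                             directed, dst, probs)
            lp2 = _step_logp(mid, i1, j1, phi, codes, acov, dcov, directed,
                             dst, probs)
            dlogf = lp1 + lp2 - logp[r] - logp[r + 1]
            if math.log(1.0 - gen.random()) < dlogf:
                steps[r, 0], steps[r, 1] = i2, j2
                steps[r + 1, 0], steps[r + 1, 1] = i1, j1
                states[r + 1] = mid
                logp[r] = lp1
                logp[r + 1] = lp2
                n_acc += 1

        elif mv == 3:
            # insert a stay step of actor i before position r
            r = int(gen.random() * (R + 1))
            if r > R:
                r = R
            i = int(gen.random() * n)
            if i >= n:
                i = n - 1
            lp1 = _step_logp(states[r], i, i, phi, codes, acov, dcov,
                             directed, dst, probs)
            dlogf = llamdt - math.log(R + 1.0) - logn + lp1
            nstays_new = _count_stays(steps, R) + 1
            lq_fwd = math.log(pm[3]) - math.log(R + 1.0) - logn
            lq_rev = math.log(pm[4]) - math.log(float(nstays_new))
            if math.log(1.0 - gen.random()) < dlogf + lq_rev - lq_fwd:
                for t in range(R - 1, r - 1, -1):
                    steps[t + 1] = steps[t]
                    logp[t + 1] = logp[t]
                for t in range(R, r - 1, -1):
                    states[t + 1] = states[t]
                steps[r, 0] = i
                steps[r, 1] = i
                logp[r] = lp1
                R += 1
                n_acc += 1

        elif mv == 4:
            nstays = _count_stays(steps, R)
            if nstays == 0:
                continue
            k = int(gen.random() * nstays)
            if k >= nstays:
                k = nstays - 1
            r = -1
            c = -1
            for t in range(R):
                if steps[t, 0] == steps[t, 1]:
                    c += 1
                    if c == k:
                        r = t
                        break
            dlogf = -llamdt + math.log(float(R)) + logn - logp[r]
            lq_fwd = math.log(pm[4]) - math.log(float(nstays))
            lq_rev = math.log(pm[3]) - math.log(float(R)) - logn
            if math.log(1.0 - gen.random()) < dlogf + lq_rev - lq_fwd:
                for t in range(r, R - 1):
                    steps[t] = steps[t + 1]
                    logp[t] = logp[t + 1]
                for t in range(r + 1, R):
                    states[t] = states[t + 1]
                R -= 1
                n_acc += 1

        else:
            # undirected only: flip which endpoint of the pair acts
            ntog = _count_toggles(steps, R)
            if ntog == 0:
                continue
            k = int(gen.random() * ntog)
            if k >= ntog:
                k = ntog - 1
            r = -1
            c = -1
            for t in range(R):
                if steps[t, 0] != steps[t, 1]:
                    c += 1
                    if c == k:
                        r = t
                        break
            i, j = steps[r, 0], steps[r, 1]
            lp1 = _step_logp(states[r], j, i, phi, codes, acov, dcov,
                             directed, dst, probs)
            dlogf = lp1 - logp[r]
            if math.log(1.0 - gen.random()) < dlogf:
                steps[r, 0], steps[r, 1] = j, i
                logp[r] = lp1
                n_acc += 1

    return steps[:R].copy(), n_acc
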