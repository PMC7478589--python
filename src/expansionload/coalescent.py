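"""Structured-coalescent branch-length engine for expected site-frequency spectra.

Simulates genealogies of a two-deme divergence history backwards in time and
accumulates, for every branch, the time during which it subtends (i, j) sampled
lineages from population 1 and 2.  The mean of that quantity over genealogies
is proportional to the expected joint SFS cell (i, j) under the infinite-sites
model, so spectra produced here can be compared to data with a composite
likelihood whose overall scale (theta) is profiled out analytically.

Conventions (shared with :mod:`expansionload.demography`):

* time is measured backwards from the present in units of 2*Nref generations;
* deme sizes are relative to Nref; pairwise coalescence rate in deme i at time
  t is 1/nu_i(t);
* migration is scaled as M = 2*Nref*m; a lineage currently in population 1
  jumps (backwards) to population 2 at rate M12 per unit of 2*Nref
  generations, where M12 is the forward rate at which population 1 receives
  migrants from population 2 (per-generation probability m12 accumulated
  over 2*Nref generations; cross-checked against msprime in the tests);
* exponential size change acts on [0, t_split]: nu_i(t) = nu_i * exp(r_i * t)
  with r_i = log(nu_i0 / nu_i) / t_split, so nu_i(0) is the present size and
  nu_i(t_split) the size at the split.

Time-varying coalescence rates are handled by thinning (rejection sampling)
with segment caps that keep the rate bound within a factor of two of the true
rate, so acceptance stays high even under strong growth.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["expected_branchlengths"]

_LN2 = 0.6931471805599453


@njit(cache=True)
def _sim_batch(n1, n2, nu1, nu2, r1, r2, t_split, nu_anc,
               mig_start, mig_stop, m12, m21, n_reps, seed):  # pragma: no cover - jit
    np.random.seed(seed)
    n = n1 + n2
    out = np.zeros((n1 + 1, n2 + 1))
    deme = np.empty(n, np.int64)
    d1 = np.empty(n, np.int64)
    d2 = np.empty(n, np.int64)
    born = np.empty(n, np.float64)
    for _rep in range(n_reps):
        for i in range(n1):
            deme[i] = 0
            d1[i] = 1
            d2[i] = 0
        for j in range(n2):
            deme[n1 + j] = 1
            d1[n1 + j] = 0
            d2[n1 + j] = 1
        born[:] = 0.0
        k = n
        t = 0.0
        anc = t_split <= 0.0
        # a lineage's subtended counts are constant over its lifetime, so its
        # branch length is accumulated once, when it disappears by coalescing
        while k > 1:
            if anc:
                rate = 0.5 * k * (k - 1) / nu_anc
                t += np.random.exponential(1.0 / rate)
                a = np.random.randint(k)
                b = np.random.randint(k - 1)
                if b >= a:
                    b += 1
                if a > b:
                    a, b = b, a
                out[d1[a], d2[a]] += t - born[a]
                out[d1[b], d2[b]] += t - born[b]
                d1[a] += d1[b]
                d2[a] += d2[b]
                born[a] = t
                deme[b] = deme[k - 1]
                d1[b] = d1[k - 1]
                d2[b] = d2[k - 1]
                born[b] = born[k - 1]
                k -= 1
                continue
            # --- two-deme phase ---
            k1 = 0
            for idx in range(k):
                if deme[idx] == 0:
                    k1 += 1
            k2 = k - k1
            mig_on = (m12 > 0.0 or m21 > 0.0) and (t >= mig_start) and (t < mig_stop)
            tb = t_split
            if (m12 > 0.0 or m21 > 0.0):
                if (not mig_on) and (mig_start > t) and (mig_start < tb):
                    tb = mig_start
                if mig_on and (mig_stop < tb):
                    tb = mig_stop
            rmax = abs(r1)
            if abs(r2) > rmax:
                rmax = abs(r2)
            if rmax > 0.0:
                cap = t + _LN2 / rmax
                if cap < tb:
                    tb = cap
            c1 = 0.5 * k1 * (k1 - 1)
            c2 = 0.5 * k2 * (k2 - 1)
            nu1_lo = nu1 * np.exp(r1 * t)
            nu1_hi = nu1 * np.exp(r1 * tb)
            if nu1_hi < nu1_lo:
                nu1_lo = nu1_hi
            nu2_lo = nu2 * np.exp(r2 * t)
            nu2_hi = nu2 * np.exp(r2 * tb)
            if nu2_hi < nu2_lo:
                nu2_lo = nu2_hi
            b1 = c1 / nu1_lo if c1 > 0.0 else 0.0
            b2 = c2 / nu2_lo if c2 > 0.0 else 0.0
            mrate = 0.0
            if mig_on:
                mrate = k1 * m12 + k2 * m21
            total = b1 + b2 + mrate
            if total <= 0.0:
                t = tb
                if t >= t_split:
                    anc = True
                continue
            dt = np.random.exponential(1.0 / total)
            if t + dt >= tb:
                t = tb
                if t >= t_split:
                    anc = True
                continue
            t += dt
            u = np.random.random() * total
            if u < b1 + b2:
                target = 0 if u < b1 else 1
                if target == 0:
                    true_rate = c1 / (nu1 * np.exp(r1 * t))
                    accept = np.random.random() < true_rate / b1
                    kk = k1
                else:
                    true_rate = c2 / (nu2 * np.exp(r2 * t))
                    accept = np.random.random() < true_rate / b2
                    kk = k2
                if accept:
                    a = np.random.randint(kk)
                    b = np.random.randint(kk - 1)
                    if b >= a:
                        b += 1
                    # map ordinals within the deme to lineage slots
                    ia = -1
                    ib = -1
                    seen = 0
                    for idx in range(k):
                        if deme[idx] == target:
                            if seen == a:
                                ia = idx
                            if seen == b:
                                ib = idx
                            seen += 1
                    if ia > ib:
                        ia, ib = ib, ia
                    out[d1[ia], d2[ia]] += t - born[ia]
                    out[d1[ib], d2[ib]] += t - born[ib]
                    d1[ia] += d1[ib]
                    d2[ia] += d2[ib]
                    born[ia] = t
                    deme[ib] = deme[k - 1]
                    d1[ib] = d1[k - 1]
                    d2[ib] = d2[k - 1]
                    born[ib] = born[k - 1]
                    k -= 1
            else:
                u2 = u - b1 - b2
                if u2 < k1 * m12:
                    src = 0
                    ord_ = np.random.randint(k1)
                else:
                    src = 1
                    ord_ = np.random.randint(k2)
                seen = 0
                for idx in range(k):
                    if deme[idx] == src:
                        if seen == ord_:
                            deme[idx] = 1 - src
                            break
                        seen += 1
    return out


def expected_branchlengths(n1, n2, *, nu1=1.0, nu2=1.0, nu1_0=None, nu2_0=None,
                           t_split=0.0, nu_anc=1.0, mig_start=0.0, mig_stop=0.0,
                           m12=0.0, m21=0.0, n_reps=10_000, seed=0):
    """Mean branch length subtending (i, j) leaves, per genealogy.

    Returns an (n1+1, n2+1) array whose (i, j) entry is the expected total
    length (in units of 2*Nref generations) of branches ancestral to exactly
    i of the n1 population-1 samples and j of the n2 population-2 samples.
    Multiplying by theta/2 per site gives the expected joint SFS.

    ``nu1_0``/``nu2_0`` are the sizes at ``t_split`` when exponential growth
    is modelled; they default to the present sizes (constant size).
    """
    if n1 < 0 or n2 < 0 or n1 + n2 < 2:
        raise ValueError("need at least two sampled lineages")
    for name, v in (("nu1", nu1), ("nu2", nu2), ("nu_anc", nu_anc)):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be positive and finite, got {v}")
    if t_split < 0 or mig_start < 0 or mig_stop < mig_start:
        raise ValueError("invalid time parameters")
    if m12 < 0 or m21 < 0 or not np.isfinite(m12 + m21):
        raise ValueError("migration rates must be non-negative and finite")
    r1 = r2 = 0.0
    if t_split > 0:
        if nu1_0 is not None and nu1_0 != nu1:
            r1 = np.log(nu1_0 / nu1) / t_split
        if nu2_0 is not None and nu2_0 != nu2:
            r2 = np.log(nu2_0 / nu2) / t_split
    out = _sim_batch(int(n1), int(n2), float(nu1), float(nu2), float(r1),
                     float(r2), float(t_split), float(nu_anc),
                     float(mig_start), float(mig_stop), float(m12), float(m21),
                     int(n_reps), int(seed) % 2**31)
    return out / n_reps
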