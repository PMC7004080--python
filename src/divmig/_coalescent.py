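"""Low-level structured-coalescent kernels.

Two-deme time-inhomogeneous coalescent in units of 2*N_ref generations:
per-pair coalescence rate 1/nu_d within deme d, per-lineage backward
migration rate out of deme 1 equal to M12 (= 2*N_ref*m12, the scaled
fraction of deme-1 individuals replaced by deme-2 migrants each
generation) and symmetrically M21.  Epochs are passed in backward order
(present first); entering the final epoch merges every lineage into the
ancestral deme (index 0), whose size is the reference size 1.

Kernels are numba-jitted for throughput; they fall back to pure Python if
numba is unavailable so the package degrades gracefully.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


@njit(cache=False)
def branch_length_moments(
    n1, n2, dur, nu1, nu2, m12, m21, n_reps, seed, l_sum, l_sqsum
):
    """Accumulate first and second moments of per-class branch lengths.

    ``l_sum``/``l_sqsum`` are (n1+1, n2+1) accumulators; for each of
    ``n_reps`` independent genealogies the total branch length subtending
    exactly (i, j) of the sampled haplotypes is added (and its square).
    Expected AFS entry (i, j) = (theta/2) * l_sum[i, j] / n_reps.
    """
    np.random.seed(seed)
    n = n1 + n2
    n_epochs = dur.shape[0]
    deme = np.empty(n, np.int64)
    ic = np.empty(n, np.int64)
    jc = np.empty(n, np.int64)
    l_loc = np.zeros((n1 + 1, n2 + 1))
    for _rep in range(n_reps):
        for a in range(n1 + 1):
            for b in range(n2 + 1):
                l_loc[a, b] = 0.0
        for x in range(n1):
            deme[x] = 0
            ic[x] = 1
            jc[x] = 0
        for x in range(n2):
            deme[n1 + x] = 1
            ic[n1 + x] = 0
            jc[n1 + x] = 1
        k = n
        e = 0
        t = 0.0
        while k > 1:
            k1 = 0
            for x in range(k):
                if deme[x] == 0:
                    k1 += 1
            k2 = k - k1
            c1 = 0.5 * k1 * (k1 - 1) / nu1[e]
            c2 = 0.5 * k2 * (k2 - 1) / nu2[e]
            mg = k1 * m12[e] + k2 * m21[e]
            total_rate = c1 + c2 + mg
            advance = False
            dt = 0.0
            if total_rate <= 0.0:
                advance = True
            else:
                dt = np.random.exponential(1.0 / total_rate)
                if e < n_epochs - 1 and t + dt > dur[e]:
                    advance = True
            if advance:
                rest = dur[e] - t
                for x in range(k):
                    l_loc[ic[x], jc[x]] += rest
                e += 1
                t = 0.0
                if e == n_epochs - 1:
                    for x in range(k):
                        deme[x] = 0
                continue
            for x in range(k):
                l_loc[ic[x], jc[x]] += dt
            t += dt
            u = np.random.random() * total_rate
            if u < c1 + c2:
                d = 0 if u < c1 else 1
                kd = k1 if d == 0 else k2
                a = np.random.randint(kd)
                b = np.random.randint(kd - 1)
                if b >= a:
                    b += 1
                ia = -1
                ib = -1
                seen = 0
                for x in range(k):
                    if deme[x] == d:
                        if seen == a:
                            ia = x
                        if seen == b:
                            ib = x
                        seen += 1
                ic[ia] += ic[ib]
                jc[ia] += jc[ib]
                deme[ib] = deme[k - 1]
                ic[ib] = ic[k - 1]
                jc[ib] = jc[k - 1]
                k -= 1
            else:
                v = u - c1 - c2
                if v < k1 * m12[e]:
                    a = np.random.randint(k1)
                    seen = 0
                    for x in range(k):
                        if deme[x] == 0:
                            if seen == a:
                                deme[x] = 1
                                break
                            seen += 1
                else:
                    a = np.random.randint(k2)
                    seen = 0
                    for x in range(k):
                        if deme[x] == 1:
                            if seen == a:
                                deme[x] = 0
                                break
                            seen += 1
        for a in range(n1 + 1):
            for b in range(n2 + 1):
                l_sum[a, b] += l_loc[a, b]
                l_sqsum[a, b] += l_loc[a, b] * l_loc[a, b]


@njit(cache=False)
def simulate_sites(
    n1, n2,
    dur_a, nu1_a, nu2_a, m12_a, m21_a,
    dur_b, nu1_b, nu2_b, m12_b, m21_b,
    p_class_a, l_bound_a, l_bound_b,
    n_sites, seed, out_mask1, out_mask2, out_tmrca, out_class,
):
    """Simulate unlinked segregating sites, one independent genealogy each.

    Per site: a migration class is drawn (class a with probability
    ``p_class_a``; pass identical epoch arrays and p = 1 for single-class
    models) and a genealogy simulated under it.  The genealogy is accepted
    with probability total_length / l_bound (rejection sampling), which
    length-biases accepted genealogies exactly as conditioning on a
    segregating site does under infinite sites; a single mutation is then
    placed uniformly on the branches, so every site is biallelic and
    segregating by construction.  ``l_bound`` must be a near-certain upper
    bound on total branch length (lengths above it are accepted outright;
    the bias is of the order of the bound's tail probability).  Outputs
    are per-site derived-allele bitmasks (tip x of pop p sets bit x of
    mask p), the genealogy TMRCA, and the class indicator (0 = class a).
    """
    np.random.seed(seed)
    n = n1 + n2
    deme = np.empty(n, np.int64)
    m1 = np.empty(n, np.int64)
    m2 = np.empty(n, np.int64)
    blen = np.empty(n, np.float64)
    rec_m1 = np.empty(2 * n, np.int64)
    rec_m2 = np.empty(2 * n, np.int64)
    rec_len = np.empty(2 * n, np.float64)
    for s in range(n_sites):
        accepted = False
        while not accepted:
            use_a = np.random.random() < p_class_a
            if use_a:
                n_epochs = dur_a.shape[0]
            else:
                n_epochs = dur_b.shape[0]
            for x in range(n1):
                deme[x] = 0
                m1[x] = np.int64(1) << x
                m2[x] = 0
                blen[x] = 0.0
            for x in range(n2):
                deme[n1 + x] = 1
                m1[n1 + x] = 0
                m2[n1 + x] = np.int64(1) << x
                blen[n1 + x] = 0.0
            k = n
            e = 0
            t = 0.0
            elapsed = 0.0
            n_rec = 0
            while k > 1:
                if use_a:
                    nu1e = nu1_a[e]
                    nu2e = nu2_a[e]
                    m12e = m12_a[e]
                    m21e = m21_a[e]
                    dure = dur_a[e]
                else:
                    nu1e = nu1_b[e]
                    nu2e = nu2_b[e]
                    m12e = m12_b[e]
                    m21e = m21_b[e]
                    dure = dur_b[e]
                k1 = 0
                for x in range(k):
                    if deme[x] == 0:
                        k1 += 1
                k2 = k - k1
                c1 = 0.5 * k1 * (k1 - 1) / nu1e
                c2 = 0.5 * k2 * (k2 - 1) / nu2e
                mg = k1 * m12e + k2 * m21e
                total_rate = c1 + c2 + mg
                advance = False
                dt = 0.0
                if total_rate <= 0.0:
                    advance = True
                else:
                    dt = np.random.exponential(1.0 / total_rate)
                    if e < n_epochs - 1 and t + dt > dure:
                        advance = True
                if advance:
                    rest = dure - t
                    for x in range(k):
                        blen[x] += rest
                    elapsed += rest
                    e += 1
                    t = 0.0
                    if e == n_epochs - 1:
                        for x in range(k):
                            deme[x] = 0
                    continue
                for x in range(k):
                    blen[x] += dt
                elapsed += dt
                t += dt
                u = np.random.random() * total_rate
                if u < c1 + c2:
                    d = 0 if u < c1 else 1
                    kd = k1 if d == 0 else k2
                    a = np.random.randint(kd)
                    b = np.random.randint(kd - 1)
                    if b >= a:
                        b += 1
                    ia = -1
                    ib = -1
                    seen = 0
                    for x in range(k):
                        if deme[x] == d:
                            if seen == a:
                                ia = x
                            if seen == b:
                                ib = x
                            seen += 1
                    rec_m1[n_rec] = m1[ia]
                    rec_m2[n_rec] = m2[ia]
                    rec_len[n_rec] = blen[ia]
                    n_rec += 1
                    rec_m1[n_rec] = m1[ib]
                    rec_m2[n_rec] = m2[ib]
                    rec_len[n_rec] = blen[ib]
                    n_rec += 1
                    m1[ia] |= m1[ib]
                    m2[ia] |= m2[ib]
                    blen[ia] = 0.0
                    deme[ib] = deme[k - 1]
                    m1[ib] = m1[k - 1]
                    m2[ib] = m2[k - 1]
                    blen[ib] = blen[k - 1]
                    k -= 1
                else:
                    v = u - c1 - c2
                    if v < k1 * m12e:
                        a = np.random.randint(k1)
                        seen = 0
                        for x in range(k):
                            if deme[x] == 0:
                                if seen == a:
                                    deme[x] = 1
                                    break
                                seen += 1
                    else:
                        a = np.random.randint(k2)
                        seen = 0
                        for x in range(k):
                            if deme[x] == 1:
                                if seen == a:
                                    deme[x] = 0
                                    break
                                seen += 1
            total_len = 0.0
            for r in range(n_rec):
                total_len += rec_len[r]
            l_bound = l_bound_a if use_a else l_bound_b
            if np.random.random() * l_bound > total_len:
                continue
            target = np.random.random() * total_len
            acc = 0.0
            chosen = n_rec - 1
            for r in range(n_rec):
                acc += rec_len[r]
                if target < acc:
                    chosen = r
                    break
            out_mask1[s] = rec_m1[chosen]
            out_mask2[s] = rec_m2[chosen]
            out_tmrca[s] = elapsed
            out_class[s] = 0 if use_a else 1
            accepted = True
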