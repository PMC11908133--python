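"""Independent brute-force oracles for the structure-inference stage.

Deliberately written with plain Python loops and scipy.stats.binom so
they share no code path with the vectorized implementation in
clonedyn.inference.
"""

import math

from scipy.stats import binom as sp_binom


def brute_partitions(labels):
    """All set partitions by inserting each element into every block."""
    labels = list(labels)
    if not labels:
        return []
    parts = [[[labels[0]]]]
    for lab in labels[1:]:
        nxt = []
        for p in parts:
            for i in range(len(p)):
                q = [list(b) for b in p]
                q[i].append(lab)
                nxt.append(q)
            nxt.append([list(b) for b in p] + [[lab]])
        parts = nxt
    return [tuple(tuple(b) for b in p) for p in parts]


def _mean(xs):
    return sum(xs) / len(xs)


def _lead(trajs, block):
    return min(block, key=lambda lab: (-_mean(list(trajs[lab].vafs)), lab))


def _interp(t, xs, ys):
    """Piecewise-linear interpolation clamped at the ends."""
    if t <= xs[0]:
        return ys[0]
    if t >= xs[-1]:
        return ys[-1]
    for i in range(len(xs) - 1):
        if xs[i] <= t <= xs[i + 1]:
            w = (t - xs[i]) / (xs[i + 1] - xs[i])
            return ys[i] * (1 - w) + ys[i + 1] * w
    raise AssertionError


def _competitor_mass(trajs, all_leads, own_lead, age, params):
    """Data-estimated summed size of the other leads at one age."""
    df, N = params.diploid_factor, params.n_wildtype
    vafs = {
        lab: _interp(age, list(trajs[lab].ages), list(trajs[lab].vafs))
        for lab in all_leads
    }
    dfv = min(max(df * sum(vafs.values()), 0.0), 0.98)
    s_total = dfv * N / (1.0 - dfv)
    return sum(vafs[lab] * df * (N + s_total) for lab in all_leads if lab != own_lead)


def _block_loglik_at_s(trajs, block, s, params, all_leads):
    """Profiled clone log-likelihood at one fitness value (plain loops)."""
    df, N, floor = params.diploid_factor, params.n_wildtype, params.error_floor
    lead = _lead(trajs, block)

    def obs_ll(t, a, lead_size):
        total = 0.0
        for o in t.observations:
            x = math.exp(s * (o.age - a)) if o.age >= a else 0.0
            xd = lead_size(o.age) if lead_size else x
            s_other = _competitor_mass(trajs, all_leads, lead, o.age, params)
            p = (
                min(x / (df * (N + xd + s_other)), 1.0 - floor)
                if x > 0
                else floor
            )
            total += float(sp_binom.logpmf(int(o.alt_reads), int(o.depth), p))
        return total

    t_lead = trajs[lead]
    best_ll, best_a = -math.inf, None
    for a in range(0, int(math.floor(t_lead.ages[0])) + 1):
        ll = obs_ll(t_lead, a, None)
        if ll > best_ll:
            best_ll, best_a = ll, a
    total = best_ll

    for lab in sorted(block):
        if lab == lead:
            continue
        t = trajs[lab]
        grid = list(range(0, int(math.floor(t.ages[0])) + 1))
        allowed = [a for a in grid if a >= best_a] or grid

        def lead_size(age):
            return math.exp(s * (age - best_a)) if age >= best_a else 0.0

        best_v = -math.inf
        for a in allowed:
            ll = obs_ll(t, a, lead_size)
            if ll > best_v:
                best_v = ll
        total += best_v
    return total


def brute_log_evidence(trajectories, partition, grid, params):
    """Nested-loop evidence: product over blocks of grid-averaged likelihood."""
    trajs = {t.label: t for t in trajectories}
    leads = {tuple(b): _lead(trajs, b) for b in partition}
    total = 0.0
    for block in partition:
        all_leads = sorted(leads.values())
        lls = [_block_loglik_at_s(trajs, block, s, params, all_leads) for s in grid]
        m = max(lls)
        total += m + math.log(sum(math.exp(l - m) for l in lls)) - math.log(len(grid))
    return total


def brute_best_partition(trajectories, grid, params):
    labels = sorted(t.label for t in trajectories)
    best, best_ev, best_nb = None, -math.inf, -1
    for p in brute_partitions(labels):
        ev = brute_log_evidence(trajectories, p, grid, params)
        if ev > best_ev + 1e-12 or (abs(ev - best_ev) <= 1e-12 and len(p) > best_nb):
            best, best_ev, best_nb = p, ev, len(p)
    return best, best_ev
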