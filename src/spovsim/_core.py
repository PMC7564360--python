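"""Compiled inner loop of the season engine.

Kept separate from :mod:`spovsim.season` so the numba signature stays
readable.  See :mod:`spovsim.season` for the step ordering and the RNG draw
protocol; :mod:`spovsim.micro` mirrors both in pure Python.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_season_core"]


@njit(cache=True)
def _poisson_knuth(rng, lam):
    # Knuth multiplication method; lambda is small (maxenc <= a few)
    limit = np.exp(-lam)
    k = 0
    prod = rng.random()
    while prod > limit:
        prod *= rng.random()
        k += 1
    return k


@njit(cache=True)
def run_season_core(
    rng,
    days,
    maxenc,
    encounter_mode,  # 0 fixed, 1 poisson, 2 thinned by eligible density
    pspov,
    pmate,
    escape_coeff,
    meal_gain,
    male_mort,
    mfcl_mated_only,
    satiated_lethal,
    approach_attack_virgins,
    cohab_mate_first,
    withdrawal_mode,  # 0 none, 1 gravid (mated & satiated), 2 satiated
    f_mat,
    f_cw,
    f_cond,
    f_maxcond,
    f_sat,
    f_mated,
    f_father,
    f_resident,
    f_alive,
    f_kills,
    f_mort,
    f_intake,
    f_attack,
    m_allele,
    m_mat,
    m_alive,
    m_cohab,
    m_matings,
    log_events,
    events,
):
    nf = f_mat.shape[0]
    nm = m_mat.shape[0]
    n_ev = 0
    f_bg_deaths = 0
    m_bg_deaths = 0
    m_cannibalized = 0
    targets = np.empty(nf if nf > 0 else 1, np.int64)
    eligible = np.zeros(nf if nf > 0 else 1, np.bool_)

    for d in range(days):
        # (2) background mortality: females by index, then males by index
        for i in range(nf):
            if f_alive[i] and f_mat[i] <= d:
                if rng.random() < f_mort[i]:
                    f_alive[i] = False
                    f_bg_deaths += 1
                    r = f_resident[i]
                    if r >= 0:
                        m_cohab[r] = -1
                        f_resident[i] = -1
                    if log_events:
                        events[n_ev, 0] = d
                        events[n_ev, 1] = 1
                        events[n_ev, 2] = -1
                        events[n_ev, 3] = i
                        n_ev += 1
        for j in range(nm):
            if m_alive[j] and m_mat[j] <= d:
                if rng.random() < male_mort:
                    m_alive[j] = False
                    m_bg_deaths += 1
                    c = m_cohab[j]
                    if c >= 0:
                        f_resident[c] = -1
                        m_cohab[j] = -1
                    if log_events:
                        events[n_ev, 0] = d
                        events[n_ev, 1] = 2
                        events[n_ev, 2] = j
                        events[n_ev, 3] = -1
                        n_ev += 1

        # (3) feeding
        for i in range(nf):
            if f_alive[i] and f_mat[i] <= d and not f_sat[i]:
                f_cond[i] += rng.random() * f_intake[i]
                if f_cond[i] >= f_maxcond[i]:
                    f_cond[i] = f_maxcond[i]
                    f_sat[i] = True

        # encounter-pool eligibility (fixed for steps 4-5: females cannot
        # die or change withdrawal status during them except via satiation
        # from a male meal, which is rechecked below)
        n_eligible = 0
        for i in range(nf):
            ok = f_alive[i] and f_mat[i] <= d
            if ok and withdrawal_mode == 1:
                ok = not (f_mated[i] and f_sat[i])
            elif ok and withdrawal_mode == 2:
                ok = not f_sat[i]
            eligible[i] = ok
            if ok:
                n_eligible += 1

        # (4) male search
        if n_eligible > 0:
            for j in range(nm):
                if not m_alive[j] or m_mat[j] > d or m_cohab[j] >= 0:
                    continue
                n_enc = maxenc
                if encounter_mode == 1:
                    n_enc = _poisson_knuth(rng, float(maxenc))
                elif encounter_mode == 2:
                    frac = n_eligible / nf
                    n_enc = 0
                    for _t in range(maxenc):
                        if rng.random() < frac:
                            n_enc += 1
                if n_enc > n_eligible:
                    n_enc = n_eligible
                n_targets = 0
                for _e in range(n_enc):
                    # rejection-sample a distinct eligible female
                    while True:
                        i = int(rng.integers(0, nf))
                        if not eligible[i]:
                            continue
                        dup = False
                        for t in range(n_targets):
                            if targets[t] == i:
                                dup = True
                                break
                        if not dup:
                            break
                    targets[n_targets] = i
                    n_targets += 1

                    if f_resident[i] >= 0:
                        # prior residency: the newcomer leaves
                        if log_events:
                            events[n_ev, 0] = d
                            events[n_ev, 1] = 3
                            events[n_ev, 2] = j
                            events[n_ev, 3] = i
                            n_ev += 1
                        continue

                    if not f_mated[i] and not approach_attack_virgins:
                        # virgins defer their attack decision to the
                        # cohabitation loop: the approach starts residency
                        f_resident[i] = j
                        m_cohab[j] = i
                        if log_events:
                            events[n_ev, 0] = d
                            events[n_ev, 1] = 6
                            events[n_ev, 2] = j
                            events[n_ev, 3] = i
                            n_ev += 1
                        break

                    if f_attack[i] == 1:
                        attacks = rng.random() < pspov
                    elif mfcl_mated_only:
                        attacks = f_mated[i]
                    else:
                        attacks = f_mated[i] or not f_sat[i]

                    if attacks:
                        if f_sat[i] and not satiated_lethal:
                            # a satiated female no longer feeds: her attack
                            # drives the male off unharmed
                            if log_events:
                                events[n_ev, 0] = d
                                events[n_ev, 1] = 4
                                events[n_ev, 2] = j
                                events[n_ev, 3] = i
                                n_ev += 1
                            break
                        if rng.random() < np.exp(-escape_coeff * f_cw[i]):
                            if log_events:
                                events[n_ev, 0] = d
                                events[n_ev, 1] = 4
                                events[n_ev, 2] = j
                                events[n_ev, 3] = i
                                n_ev += 1
                            break  # escaped; done searching for the day
                        m_alive[j] = False
                        m_cannibalized += 1
                        f_kills[i] += 1
                        if not f_sat[i]:
                            f_cond[i] += meal_gain
                            if f_cond[i] >= f_maxcond[i]:
                                f_cond[i] = f_maxcond[i]
                                f_sat[i] = True
                        if log_events:
                            events[n_ev, 0] = d
                            events[n_ev, 1] = 5
                            events[n_ev, 2] = j
                            events[n_ev, 3] = i
                            n_ev += 1
                        break  # male dead
                    elif not f_mated[i]:
                        f_resident[i] = j
                        m_cohab[j] = i
                        if log_events:
                            events[n_ev, 0] = d
                            events[n_ev, 1] = 6
                            events[n_ev, 2] = j
                            events[n_ev, 3] = i
                            n_ev += 1
                        break  # cohabiting; stops searching
                    # no attack, female already mated: nothing happens,
                    # male continues with his remaining encounters

        # (5) cohabitation, by female index (includes pairs formed today)
        for i in range(nf):
            j = f_resident[i]
            if j < 0:
                continue

            if cohab_mate_first:
                if rng.random() < pmate:
                    f_mated[i] = True
                    f_father[i] = m_allele[j]
                    m_matings[j] += 1
                    f_resident[i] = -1
                    m_cohab[j] = -1
                    if log_events:
                        events[n_ev, 0] = d
                        events[n_ev, 1] = 9
                        events[n_ev, 2] = j
                        events[n_ev, 3] = i
                        n_ev += 1
                    continue

            if f_attack[i] == 1:
                attacks = rng.random() < pspov
            elif mfcl_mated_only:
                attacks = f_mated[i]
            else:
                attacks = f_mated[i] or not f_sat[i]

            if attacks:
                if f_sat[i] and not satiated_lethal:
                    f_resident[i] = -1
                    m_cohab[j] = -1
                    if log_events:
                        events[n_ev, 0] = d
                        events[n_ev, 1] = 7
                        events[n_ev, 2] = j
                        events[n_ev, 3] = i
                        n_ev += 1
                elif rng.random() < np.exp(-escape_coeff * f_cw[i]):
                    f_resident[i] = -1
                    m_cohab[j] = -1
                    if log_events:
                        events[n_ev, 0] = d
                        events[n_ev, 1] = 7
                        events[n_ev, 2] = j
                        events[n_ev, 3] = i
                        n_ev += 1
                else:
                    m_alive[j] = False
                    m_cannibalized += 1
                    f_kills[i] += 1
                    if not f_sat[i]:
                        f_cond[i] += meal_gain
                        if f_cond[i] >= f_maxcond[i]:
                            f_cond[i] = f_maxcond[i]
                            f_sat[i] = True
                    f_resident[i] = -1
                    m_cohab[j] = -1
                    if log_events:
                        events[n_ev, 0] = d
                        events[n_ev, 1] = 8
                        events[n_ev, 2] = j
                        events[n_ev, 3] = i
                        n_ev += 1
            elif not cohab_mate_first:
                if rng.random() < pmate:
                    f_mated[i] = True
                    f_father[i] = m_allele[j]
                    m_matings[j] += 1
                    f_resident[i] = -1
                    m_cohab[j] = -1
                    if log_events:
                        events[n_ev, 0] = d
                        events[n_ev, 1] = 9
                        events[n_ev, 2] = j
                        events[n_ev, 3] = i
                        n_ev += 1

    return f_bg_deaths, m_bg_deaths, m_cannibalized, n_ev
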