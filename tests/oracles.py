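"""Independent brute-force re-implementations used as test oracles.

These deliberately share no code with the package: plain-Python,
row-at-a-time translations of the denominator/numerator membership rules
and of episode splitting, against which the vectorised implementations are
checked.
"""

import datetime as dt


def _d(iso):
    return dt.date.fromisoformat(iso) if iso else None


def prevalence_flags_one_row(event, tod, death, year_start, year_end):
    """The five membership/follow-up rules, traced literally per row.

    ``event``/``tod``/``death`` are ISO strings or None.  Returns a dict of
    the four flags plus follow-up in years (365.25-day years).
    """
    ev, td, dd = _d(event), _d(tod), _d(death)
    ys, ye = _d(year_start), _d(year_end)
    in_year = ev is not None and ys <= ev <= ye
    tod_after_event = ev is not None and (td is None or td > ev)
    incident_numerator = in_year and tod_after_event
    incident_denominator = (ev is None or ev >= ys) and (td is None or td > ys)
    prevalent_numerator = ev is not None and ev <= ye and tod_after_event
    prevalent_denominator = td is None or td > ys
    end = ye
    if td is not None and td < end:
        end = td
    if dd is not None and dd < end:
        end = dd
    followup = max(0, (end - ys).days) / 365.25
    return {
        "incident_numerator": incident_numerator,
        "incident_denominator": incident_denominator,
        "prevalent_numerator": prevalent_numerator,
        "prevalent_denominator": prevalent_denominator,
        "followup": followup,
    }


def split_episodes(rows, cut_times, on_existing="flip", state0=None):
    """Row-at-a-time episode splitting oracle.

    ``rows`` is a list of (entry, exit, state) tuples for one subject;
    ``cut_times`` a list with one cut time (or None) applied to every row.
    Returns the new (entry, exit, state) list sorted by entry.
    """
    out = []
    for (entry, exit_, state), t in zip(rows, cut_times):
        if state0 is not None:
            state = state0

        def bump(s):
            if state0 is not None:
                return 1
            return (1 - s) if on_existing == "flip" else s + 1

        if t is None or t > exit_:
            out.append((entry, exit_, state))
        elif t <= entry:
            out.append((entry, exit_, bump(state)))
        else:
            out.append((entry, t - 1, state))
            out.append((t, exit_, bump(state)))
    return sorted(out)
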