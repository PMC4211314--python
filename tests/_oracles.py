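"""Independent reference implementations used as oracles by the tests.

Deliberately naive: dictionary-based edge matching, exhaustive per-anchor
selection enumeration, pairwise consistency — no shared machinery with the
package's indexed activation or plan-based route search.
"""

import itertools

from hypermem import MISSING


def naive_activation(network, probe_edges, N_m=0):
    """Activated edges per anchor by scanning every stored edge."""
    activated = {}
    for pe in probe_edges:
        if all(v is MISSING for v in pe.vals):
            continue
        pd = dict(zip(pe.attrs, pe.vals))
        hits = []
        for me in sorted(network.edges_at(pe.anchor)):
            md = dict(zip(me.attrs, me.vals))
            matched = mismatched = 0
            for attr in set(pd) & set(md):
                if pd[attr] is MISSING:
                    continue
                if pd[attr] == md[attr]:
                    matched += 1
                else:
                    mismatched += 1
            if matched > N_m and mismatched == 0:
                hits.append(me)
        activated[pe.anchor] = hits
    return activated


def brute_force_verdict(network, activated, topology, d):
    """Old iff some per-anchor selection is linked where adjacent and consistent."""
    anchors = sorted(activated)
    if not anchors or any(not activated[a] for a in anchors):
        return "new"
    for selection in itertools.product(*(activated[a] for a in anchors)):
        ok = True
        for ea, eb in itertools.combinations(selection, 2):
            da, db = dict(zip(ea.attrs, ea.vals)), dict(zip(eb.attrs, eb.vals))
            if any(da[a] != db[a] for a in set(da) & set(db)):
                ok = False
                break
        if not ok:
            continue
        for i in range(len(anchors)):
            j = (i + 1) % len(anchors)
            if j == 0 and topology == "line":
                break
            adjacent = (
                (anchors[i] + 1) % d == anchors[j]
                if topology == "ring"
                else anchors[i] + 1 == anchors[j]
            )
            if adjacent and not network.has_link(selection[i], selection[j]):
                ok = False
                break
        if ok:
            return "old"
    return "new"
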