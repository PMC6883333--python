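"""QTL-driven social-network reconstruction among individuals.

Each individual carries a *marginal genotypic value* at every detected
QTL: the expected genotype-combination mean for its own genotype, averaged
over partner genotypes at their observed frequencies.  Laying the QTL out
along an axis (genomic order by default) gives every individual a
genotypic profile; treating that axis as the integration variable of a
dynamic system, inter-individual dependence is modelled as

    dG_i/dt = f_i(G_i; theta_i) + sum_{j != i} f_ij(G_j; theta_ij)

with polynomial components.  Profiles are smoothed with an orthogonal
(Legendre) polynomial basis, derivatives taken from the smooth, and the
dependent components selected by L1-penalised regression with an in-degree
cap.  A selected component f_ij is a directed edge j -> i whose weight is
the mean of f_ij along the axis and whose sign is the sign of that mean.

Edge-sign patterns classify each unordered pair: reciprocal positive
edges are mutualism, reciprocal negative antagonism, a lone negative edge
is aggression by its sender, a lone positive edge altruism by its sender;
opposite-signed reciprocal edges fall outside the four canonical types and
are reported separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import savgol_filter
from sklearn.linear_model import Lasso, LassoLarsCV, LassoLarsIC
from sklearn.model_selection import KFold

from .gio import MarkerSet

__all__ = [
    "GenotypicProfileMatrix",
    "SocialNetwork",
    "marginal_genotypic_values",
    "infer_social_network",
    "classify_edges",
    "find_hubs",
    "exclusion_experiment",
]


@dataclass
class GenotypicProfileMatrix:
    """Individuals x QTL matrix of marginal genotypic values."""

    values: pd.DataFrame  # rows = individuals, columns = QTL markers
    qtl_kinds: dict  # marker -> set of descriptor kinds it was detected for
    imputed: list = field(default_factory=list)  # (individual, marker) pairs

    @property
    def individuals(self) -> list:
        return list(self.values.index)

    @property
    def qtl(self) -> list:
        return list(self.values.columns)


def marginal_genotypic_values(
    scan_results,
    ms: MarkerSet,
    qtl: list,
    kind: str = None,
) -> pd.DataFrame:
    """Marginal genotypic value of every individual at the listed QTL.

    For individual ``i`` at QTL ``q``, the entry is the frequency-weighted
    average of the scan's combo means over the partner genotype, at ``i``'s
    own genotype; partner-genotype frequencies are the observed genotype
    frequencies at the marker.  A missing genotype is imputed with the
    individual's row mean across the other QTL (flagged in
    ``df.attrs['imputed']``).
    """
    kind = kind or scan_results.model.descriptor
    sig = set(scan_results.significant_markers)
    cols = {}
    for marker in qtl:
        if marker not in scan_results.model.marker_set.markers:
            raise KeyError(f"QTL {marker!r} absent from the scan")
        if marker not in sig:
            warnings.warn(f"QTL {marker!r} is not significant in the scan")
        detail = scan_results.marker_detail(marker)
        g = ms.column(marker)
        present = g[g >= 0]
        codes = np.unique(present)
        freqs = {int(c): float((present == c).mean()) for c in codes}
        symmetric = kind in ("mu", "an")

        def mean_for(own: int) -> float:
            tot, wsum = 0.0, 0.0
            for partner, f in freqs.items():
                key = ((min(own, partner), max(own, partner)) if symmetric
                       else (own, partner))
                m = detail.combo_means.get(key, np.nan)
                if np.isfinite(m):
                    tot += f * m
                    wsum += f
            return tot / wsum if wsum > 0 else np.nan

        lut = {int(c): mean_for(int(c)) for c in codes}
        cols[marker] = np.array(
            [lut.get(int(gi), np.nan) if gi >= 0 else np.nan for gi in g]
        )
    df = pd.DataFrame(cols, index=ms.individuals)
    imputed = []
    if df.isna().any().any():
        row_means = df.mean(axis=1)
        for ind in df.index[df.isna().any(axis=1)]:
            for q in df.columns[df.loc[ind].isna()]:
                df.loc[ind, q] = row_means[ind]
                imputed.append((ind, q))
    df.attrs["imputed"] = imputed
    return df


def build_profile_matrix(scans: dict, ms: MarkerSet,
                         exclude: str = None) -> GenotypicProfileMatrix:
    """Union of per-descriptor significant QTL into one profile matrix.

    ``scans`` maps descriptor kind -> fitted scan results.  QTL are laid
    out in genomic order; excluding a kind drops the QTL detected *only*
    for that kind.
    """
    kinds_of = {}
    for kind, res in scans.items():
        for mk in res.significant_markers:
            kinds_of.setdefault(mk, set()).add(kind)
    keep = [mk for mk, ks in kinds_of.items()
            if exclude is None or ks != {exclude}]
    order = {mk: i for i, mk in enumerate(ms.markers)}
    keep.sort(key=lambda mk: order[mk])
    pieces = []
    for kind, res in scans.items():
        if kind == exclude:
            continue
        mine = [mk for mk in keep if kind in kinds_of[mk]]
        if mine:
            pieces.append(marginal_genotypic_values(res, ms, mine, kind))
    if not pieces:
        return GenotypicProfileMatrix(
            values=pd.DataFrame(index=ms.individuals),
            qtl_kinds={},
        )
    merged = pd.concat(pieces, axis=1)
    merged = merged.loc[:, ~merged.columns.duplicated()]
    merged = merged[[mk for mk in keep if mk in merged.columns]]
    return GenotypicProfileMatrix(values=merged,
                                  qtl_kinds={mk: kinds_of[mk] for mk in keep})


# ---------------------------------------------------------------------------
# network container
# ---------------------------------------------------------------------------

@dataclass
class SocialNetwork:
    """Directed, signed, weighted interaction network among individuals."""

    nodes: list
    edges: pd.DataFrame  # from, to, weight, sign
    pair_labels: pd.DataFrame = None  # a, b, label (unordered, a < b order)
    hubs: list = field(default_factory=list)
    degenerate: bool = False

    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for _, e in self.edges.iterrows():
            g.add_edge(e["from"], e["to"], weight=e["weight"],
                       sign=int(e["sign"]))
        return g

    def degree(self) -> pd.Series:
        counts = pd.Series(0, index=pd.Index(self.nodes, name="node"))
        for col in ("from", "to"):
            vc = self.edges[col].value_counts()
            counts = counts.add(vc, fill_value=0)
        return counts.astype(int)

    def edge_counts_by_type(self) -> dict:
        if self.pair_labels is None or len(self.pair_labels) == 0:
            return {}
        return self.pair_labels["label"].value_counts().to_dict()

    def to_dot(self) -> str:
        lines = ["digraph social {"]
        for n in self.nodes:
            attr = ' [color=red]' if n in self.hubs else ""
            lines.append(f'  "{n}"{attr};')
        for _, e in self.edges.iterrows():
            style = "normal" if e["sign"] > 0 else "tee"
            lines.append(
                f'  "{e["from"]}" -> "{e["to"]}" '
                f'[weight={e["weight"]:.4g}, arrowhead={style}];'
            )
        lines.append("}")
        return "\n".join(lines)

    def summary(self) -> str:
        by_type = self.edge_counts_by_type()
        lines = [
            f"Social network: {len(self.nodes)} nodes, "
            f"{len(self.edges)} directed edges, {len(self.hubs)} hubs",
        ]
        for label, cnt in sorted(by_type.items()):
            lines.append(f"  {label}: {cnt} pairs")
        if self.degenerate:
            lines.append("  [degenerate: profiles carry no usable contrast]")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _smooth_profiles(values: np.ndarray, basis_order: int,
                     window: int = None):
    """Local polynomial (Savitzky-Golay) smooth + derivative of each row.

    The polynomial basis of order ``basis_order`` is fitted in a sliding
    window rather than globally: a single global low-order polynomial
    would project every profile into the same (order+1)-dimensional
    function space, leaving the downstream regression design
    rank-deficient and the couplings unidentifiable.
    """
    n, q = values.shape
    if window is None:
        window = min(q if q % 2 else q - 1, max(basis_order + 2, 9))
    if window % 2 == 0:
        window += 1
    window = min(window, q if q % 2 else q - 1)
    order = min(basis_order, window - 1)
    # unit axis spacing: the QTL index is the integration variable
    smooth = savgol_filter(values, window, order, axis=1)
    deriv = savgol_filter(values, window, order, deriv=1, delta=1.0, axis=1)
    t = np.arange(q, dtype=float)
    return t, smooth, deriv


def _component_features(x: np.ndarray, degree: int) -> np.ndarray:
    """Polynomial features (x, x², ...) of one profile, centred."""
    feats = np.column_stack([x ** d for d in range(1, degree + 1)])
    return feats - feats.mean(axis=0)


def infer_social_network(
    profiles,
    basis_order: int = 4,
    max_in_degree: int = 3,
    sparsity=None,
    seed: int = 0,
    component_degree: int = 1,
    rel_threshold: float = 0.1,
    n_null_shifts: int = 150,
    edge_alpha: float = 0.1,
) -> SocialNetwork:
    """Infer the directed, signed, weighted network from genotypic profiles.

    Each node's profile is smoothed with a local polynomial basis of order
    ``basis_order`` along the QTL axis and its derivative estimated from
    the smooth; the derivative is regressed on polynomial components of
    the node's own profile and of every candidate partner's profile with
    an L1 penalty, and the incoming components surviving selection (capped
    at ``max_in_degree``, after a relative-contribution filter) become
    directed edges.  Edge weight is the average marginal effect of the
    partner's profile on the node's derivative (the component's constant
    level is absorbed by the regression intercept and not identifiable);
    its sign gives the edge sign.

    Parameters
    ----------
    profiles
        :class:`GenotypicProfileMatrix` or DataFrame (individuals x QTL).
    basis_order
        Order of the local smoothing polynomial (needs at least
        ``basis_order + 2`` QTL columns).
    max_in_degree
        Cap on selected incoming partners per node.
    sparsity
        ``None`` (default): L1 penalty chosen per node by BIC along the
        LARS path (sparsity-consistent); ``"cv"``: 5-fold
        cross-validation; a float: fixed Lasso penalty.
    component_degree
        Polynomial degree of each component f_ij (1 = linear response).
    rel_threshold
        Minimum contribution (component SD relative to derivative SD) for
        a selected component to stay a candidate.
    n_null_shifts, edge_alpha
        Each surviving candidate must beat a rotation null: profiles are
        circularly shifted along the axis (preserving their smoothness and
        autocorrelation while destroying alignment) and the candidate's
        partial contribution — residualised against the node's own
        component and its other selected partners — must exceed the
        (1 - edge_alpha) quantile of the *maximum* shifted-candidate
        contribution.  Smooth profiles carry far fewer effective degrees
        of freedom than axis points, so penalised-likelihood selection
        alone over-selects; this gate restores specificity on independent
        profiles.  Set ``n_null_shifts=0`` to disable.

    Deterministic given ``seed`` (which fixes the shift draws and any CV
    fold order).
    """
    if isinstance(profiles, GenotypicProfileMatrix):
        df = profiles.values
    else:
        df = pd.DataFrame(profiles)
    nodes = list(df.index)
    X = df.to_numpy(dtype=float)
    n, q = X.shape
    if q < basis_order + 2:
        raise ValueError(
            f"need at least basis_order+2 = {basis_order + 2} QTL columns, "
            f"got {q}"
        )

    # no contrast between individuals -> nothing identifiable
    if np.allclose(X, X[0], atol=1e-10 * (1 + np.abs(X).max())):
        return SocialNetwork(nodes=nodes, edges=_empty_edges(),
                             pair_labels=_empty_pairs(), degenerate=True)

    t, smooth, deriv = _smooth_profiles(X, basis_order)
    scale = np.std(smooth, axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    d = component_degree
    rng = np.random.default_rng(seed)
    # one offset draw shared by every node: inference is then equivariant
    # under relabelling of the individuals
    margin = max(5, q // 16)
    offsets = rng.integers(margin, max(q - margin, margin + 1),
                           size=n_null_shifts)

    rows = []
    for i in range(n):
        others = [j for j in range(n) if j != i]
        feats = {j: _component_features(smooth[j] / scale[j, 0], d)
                 for j in range(n)}
        F = np.column_stack([feats[j] for j in [i] + others])
        y = deriv[i] - deriv[i].mean()
        if sparsity is None and q > F.shape[1] + 1:
            model = LassoLarsIC(criterion="bic")
        elif sparsity is None or sparsity == "cv":
            # short axes (fewer points than candidate features) cannot
            # support the IC's noise-variance estimate; fall back to
            # blocked cross-validation
            cv = KFold(n_splits=min(5, q), shuffle=False)
            model = LassoLarsCV(cv=cv)
        else:
            model = Lasso(alpha=float(sparsity), max_iter=50000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(F, y)
        coef = model.coef_
        sd_y = float(np.std(y)) or 1.0
        # contribution of each candidate partner's component, relative to
        # the derivative scale (skip the own-component block)
        selected = []
        for k, j in enumerate(others):
            block = coef[d * (k + 1): d * (k + 2)]
            contrib = float(np.std(F[:, d * (k + 1): d * (k + 2)] @ block))
            if contrib / sd_y > rel_threshold:
                selected.append((contrib, j, k))
        selected.sort(reverse=True)
        selected = selected[:max_in_degree]
        if not selected:
            continue
        sel = [j for _, j, _ in selected]
        if n_null_shifts:
            sel = _rotation_gate(i, sel, others, feats, deriv[i], offsets,
                                 edge_alpha)
        if not sel:
            continue
        # OLS refit on own + gated components for unbiased weights
        Fk = np.column_stack([np.ones(q)] + [feats[j] for j in [i] + sel])
        beta, *_ = np.linalg.lstsq(Fk, deriv[i], rcond=None)
        for s, j in enumerate(sel):
            b = beta[1 + d + s * d: 1 + d + (s + 1) * d]
            gj = smooth[j] / scale[j, 0]
            marg = sum(deg * b[deg - 1] * gj ** (deg - 1)
                       for deg in range(1, d + 1))
            weight = float(np.mean(marg))
            if weight == 0.0:
                continue
            rows.append((nodes[j], nodes[i], weight, int(np.sign(weight))))

    edges = pd.DataFrame(rows, columns=["from", "to", "weight", "sign"]) \
        if rows else _empty_edges()
    net = SocialNetwork(nodes=nodes, edges=edges)
    return classify_edges(net)


def _rotation_gate(i, sel, others, feats, y_i, offsets, edge_alpha):
    """Keep selected partners whose partial contribution beats a rotation
    null.

    For each candidate, the response and the candidate's component are
    residualised against the node's own component and the other selected
    partners; the observed contribution must exceed the (1 - edge_alpha)
    quantile of the maximum contribution obtained when all candidate
    profiles are circularly shifted along the axis (alignment destroyed,
    autocorrelation preserved).
    """
    q = y_i.shape[0]
    d = feats[i].shape[1]
    n_shifts = offsets.size
    C = np.column_stack([feats[j] for j in others])  # (q, d*len(others))
    kept = []
    for j in sel:
        base = np.column_stack(
            [np.ones(q), feats[i]] + [feats[k] for k in sel if k != j])
        Q, _ = np.linalg.qr(base)
        ry = y_i - Q @ (Q.T @ y_i)
        sd_r = float(np.std(ry)) or 1.0

        def block_contrib(block, ry=ry, Q=Q, sd_r=sd_r):
            br = block - Q @ (Q.T @ block)
            beta, *_ = np.linalg.lstsq(br, ry, rcond=None)
            return float(np.std(br @ beta)) / sd_r

        obs = block_contrib(feats[j])
        null_max = np.empty(n_shifts)
        for s, off in enumerate(offsets):
            Cs = np.roll(C, int(off), axis=0)
            Cr = Cs - Q @ (Q.T @ Cs)
            if d == 1:
                denom = np.einsum("qk,qk->k", Cr, Cr)
                denom[denom == 0] = 1.0
                beta = (Cr.T @ ry) / denom
                null_max[s] = float(
                    (np.abs(beta) * Cr.std(axis=0)).max()) / sd_r
            else:
                best = 0.0
                for k in range(len(others)):
                    br = Cr[:, d * k: d * (k + 1)]
                    beta, *_ = np.linalg.lstsq(br, ry, rcond=None)
                    best = max(best, float(np.std(br @ beta)) / sd_r)
                null_max[s] = best
        if obs > np.quantile(null_max, 1.0 - edge_alpha):
            kept.append(j)
    return kept


def _empty_edges() -> pd.DataFrame:
    return pd.DataFrame(columns=["from", "to", "weight", "sign"])


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(columns=["a", "b", "label", "sender"])


def classify_edges(net: SocialNetwork) -> SocialNetwork:
    """Label every connected unordered pair from its directed edge signs.

    Both directions positive -> mutualism; both negative -> antagonism;
    a single negative edge -> aggression by the sender; a single positive
    edge -> altruism by the sender; reciprocal edges of opposite sign ->
    ``aggression-with-benefit`` (outside the four canonical types).
    """
    sign = {}
    for _, e in net.edges.iterrows():
        sign[(e["from"], e["to"])] = int(e["sign"])
    rows = []
    seen = set()
    for (a, b) in list(sign):
        key = tuple(sorted((a, b), key=str))
        if key in seen:
            continue
        seen.add(key)
        s_ab = sign.get((key[0], key[1]))
        s_ba = sign.get((key[1], key[0]))
        if s_ab is not None and s_ba is not None:
            if s_ab > 0 and s_ba > 0:
                label, sender = "mutualism", None
            elif s_ab < 0 and s_ba < 0:
                label, sender = "antagonism", None
            else:
                label = "aggression-with-benefit"
                sender = key[0] if s_ab is not None and s_ab < 0 else key[1]
        else:
            present = (key[0], key[1]) if s_ab is not None else (key[1], key[0])
            s = sign[present]
            sender = present[0]
            label = "aggression" if s < 0 else "altruism"
        rows.append((key[0], key[1], label, sender))
    net.pair_labels = (pd.DataFrame(rows,
                                    columns=["a", "b", "label", "sender"])
                       if rows else _empty_pairs())
    return net


# ---------------------------------------------------------------------------
# hubs
# ---------------------------------------------------------------------------

def find_hubs(net: SocialNetwork, rule: str = "degree_sd", k: float = 1.0,
              phenotypes: dict = None) -> dict:
    """Identify hub individuals and summarise hub vs marginal structure.

    Default rule: total degree > mean + k * SD over nodes.  The summary
    reports a rank-sum comparison of hub vs non-hub phenotypes (when
    ``phenotypes`` is given) and the pair-type percentage breakdowns among
    hub-hub / hub-marginal / marginal-marginal pairs, plus directed
    aggression/altruism percentages by sender/receiver hub status.
    """
    if net.n_edges() == 0:
        raise ValueError("cannot find hubs in an empty network")
    deg = net.degree()
    if rule == "degree_sd":
        cut = deg.mean() + k * deg.std(ddof=0)
        hubs = deg.index[deg > cut].tolist()
    elif rule == "top_k":
        hubs = deg.sort_values(ascending=False).index[:int(k)].tolist()
    else:
        raise ValueError(f"unknown hub rule {rule!r}")
    net.hubs = hubs
    hubset = set(hubs)

    summary = {"hubs": hubs, "degree": deg}
    if phenotypes is not None:
        hub_vals = [phenotypes[i] for i in hubs]
        other_vals = [phenotypes[i] for i in net.nodes if i not in hubset]
        if hub_vals and other_vals:
            stat, p = stats.mannwhitneyu(hub_vals, other_vals,
                                         alternative="greater")
            summary["phenotype_ranksum"] = {
                "hub_median": float(np.median(hub_vals)),
                "marginal_median": float(np.median(other_vals)),
                "U": float(stat), "p": float(p),
            }

    def stratum(a, b):
        ha, hb = a in hubset, b in hubset
        return {2: "hub-hub", 1: "hub-marginal", 0: "marginal-marginal"}[
            ha + hb]

    pl = net.pair_labels if net.pair_labels is not None else _empty_pairs()
    for label in ("mutualism", "antagonism"):
        sub = pl[pl["label"] == label]
        breakdown = {"hub-hub": 0, "hub-marginal": 0, "marginal-marginal": 0}
        for _, row in sub.iterrows():
            breakdown[stratum(row["a"], row["b"])] += 1
        total = sum(breakdown.values())
        summary[f"{label}_pct"] = {
            s: (100.0 * c / total if total else 0.0)
            for s, c in breakdown.items()
        }
    for label in ("aggression", "altruism"):
        sub = pl[pl["label"] == label]
        breakdown = {"hub->hub": 0, "hub->marginal": 0,
                     "marginal->hub": 0, "marginal->marginal": 0}
        for _, row in sub.iterrows():
            sender = row["sender"]
            receiver = row["b"] if sender == row["a"] else row["a"]
            key = (("hub" if sender in hubset else "marginal") + "->" +
                   ("hub" if receiver in hubset else "marginal"))
            breakdown[key] += 1
        total = sum(breakdown.values())
        summary[f"{label}_pct"] = {
            s: (100.0 * c / total if total else 0.0)
            for s, c in breakdown.items()
        }
    return summary


# ---------------------------------------------------------------------------
# QTL-exclusion experiments
# ---------------------------------------------------------------------------

def exclusion_experiment(
    scans: dict,
    ms: MarkerSet,
    exclude: str = None,
    **network_kwargs,
) -> pd.DataFrame:
    """Edge-count comparison: full network vs one with a QTL class removed.

    ``scans`` maps each descriptor kind (mu/an/ag/al) to its fitted scan;
    ``exclude`` drops the QTL detected only for that kind before the
    network is rebuilt.  Returns total and per-type edge counts for the
    all-QTL network and the excluded network.
    """
    if exclude not in (None, "none", "mu", "an", "ag", "al"):
        raise ValueError(f"unknown exclusion {exclude!r}")
    if exclude == "none":
        exclude = None
    full = infer_social_network(build_profile_matrix(scans, ms),
                                **network_kwargs)
    reduced = (full if exclude is None else
               infer_social_network(build_profile_matrix(scans, ms, exclude),
                                    **network_kwargs))
    rows = []
    labels = sorted(set(full.edge_counts_by_type())
                    | set(reduced.edge_counts_by_type()))
    rows.append(("total_directed_edges", full.n_edges(), reduced.n_edges()))
    for lb in labels:
        rows.append((lb, full.edge_counts_by_type().get(lb, 0),
                     reduced.edge_counts_by_type().get(lb, 0)))
    return pd.DataFrame(rows, columns=["count", "all_qtl",
                                       f"excluding_{exclude or 'none'}"])
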