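"""Topic quality and community characterization.

Covers four post-inference steps:

* intrusion tests — case generation (five in-topic posts plus one intruder
  per case) and response scoring, including accuracy split into inter- and
  intra-group cases when topics are grouped;
* topic distances — either from intrusion confusion (harder-to-spot
  intruders mean semantically closer topics) or automatically from the
  Jensen-Shannon divergence between smoothed topic-word distributions —
  followed by a classical-MDS embedding and agglomerative merging into a
  topic hierarchy;
* community profiles — per-community topic histograms, theme proportions
  and posting intensity;
* exposure analysis — for users who posted in a focal theme (e.g. personal
  experiences), the breakdown of their communities' majority themes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import jensenshannon, squareform

from .alignment import ContingencyTable
from .graph import Partition

__all__ = [
    "IntrusionCase",
    "ThemeMap",
    "CommunityProfile",
    "ExposureReport",
    "generate_intrusion_cases",
    "score_intrusion",
    "topic_distance_matrix",
    "classical_mds",
    "build_hierarchy",
    "hierarchy_to_newick",
    "community_profiles",
    "majority_theme",
    "exposure_analysis",
    "percentages_from_counts",
]

CASE_SIZE = 6
#: Deterministic preference order used to break majority-theme ties.
THEME_TIE_ORDER = ("evidence/advocacy", "harms/conspiracies", "experiential")


@dataclass(frozen=True)
class IntrusionCase:
    """Six posts: five from ``base_topic`` and one intruder, position random."""

    case_id: str
    base_topic: int
    intruder_topic: int
    post_ids: tuple[str, ...]
    intruder_position: int

    def __post_init__(self) -> None:
        if self.base_topic == self.intruder_topic:
            raise ValueError("base and intruder topic must differ")
        if len(self.post_ids) != CASE_SIZE:
            raise ValueError(f"a case holds exactly {CASE_SIZE} posts")
        if not 0 <= self.intruder_position < CASE_SIZE:
            raise ValueError("intruder position out of range")


@dataclass
class ThemeMap:
    """Total map topic → group → theme over the non-extra topics."""

    topic_to_group: dict[int, str]
    group_to_theme: dict[str, str]

    def theme(self, topic: int) -> str:
        return self.group_to_theme[self.topic_to_group[topic]]

    def group(self, topic: int) -> str:
        return self.topic_to_group[topic]

    @property
    def themes(self) -> list[str]:
        return sorted(set(self.group_to_theme.values()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThemeMap":
        cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(
            topic_to_group={int(k): str(v) for k, v in (cfg.get("topics") or {}).items()},
            group_to_theme={str(k): str(v) for k, v in cfg["groups"].items()},
        )


def generate_intrusion_cases(
    assignment: Mapping[str, int],
    topics: Sequence[int],
    k_per_pair: int = 5,
    seed: int = 0,
) -> list[IntrusionCase]:
    """``k_per_pair`` cases for every ordered pair of distinct topics.

    Each case samples five posts from the base topic and one from the
    intruder topic, all without replacement within the case, with the
    intruder inserted at a uniform-random position. Pairs involving a topic
    with fewer than six posts are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    by_topic: dict[int, list[str]] = {t: [] for t in topics}
    for pid, t in assignment.items():
        if t in by_topic:
            by_topic[t].append(pid)
    for t in by_topic:
        by_topic[t].sort()

    cases: list[IntrusionCase] = []
    for base in topics:
        for intruder in topics:
            if base == intruder:
                continue
            if len(by_topic[base]) < CASE_SIZE or len(by_topic[intruder]) < CASE_SIZE:
                warnings.warn(
                    f"skipping pair ({base}, {intruder}): a topic has fewer "
                    f"than {CASE_SIZE} posts",
                    stacklevel=2,
                )
                continue
            for k in range(k_per_pair):
                base_posts = list(rng.choice(by_topic[base], size=5, replace=False))
                intruder_post = str(rng.choice(by_topic[intruder]))
                pos = int(rng.integers(CASE_SIZE))
                post_ids = base_posts[:pos] + [intruder_post] + base_posts[pos:]
                cases.append(
                    IntrusionCase(
                        case_id=f"{base}-{intruder}-{k}",
                        base_topic=base,
                        intruder_topic=intruder,
                        post_ids=tuple(post_ids),
                        intruder_position=pos,
                    )
                )
    return cases


def score_intrusion(
    cases: Sequence[IntrusionCase],
    responses: Mapping[str, int],
    grouping: Mapping[int, str] | ThemeMap | None = None,
) -> dict:
    """Score intrusion-test responses (chosen position per case).

    Reports the overall accuracy, the analytic chance level 1/6, and — when
    a topic grouping is supplied — accuracy over inter-group cases (base and
    intruder in different groups) and intra-group cases separately.
    """
    by_id = {c.case_id: c for c in cases}
    unknown = set(responses) - set(by_id)
    if unknown:
        raise ValueError(f"unknown case id(s): {sorted(unknown)[:3]}")
    if isinstance(grouping, ThemeMap):
        grouping = grouping.topic_to_group

    def accuracy(subset: list[IntrusionCase]) -> float | None:
        answered = [c for c in subset if c.case_id in responses]
        if not answered:
            return None
        correct = sum(
            1 for c in answered if responses[c.case_id] == c.intruder_position
        )
        return correct / len(answered)

    report = {
        "n_cases": len(cases),
        "n_responses": len(responses),
        "overall_accuracy": accuracy(list(cases)),
        "chance_level": 1.0 / CASE_SIZE,
    }
    if grouping is not None:
        inter = [c for c in cases if grouping[c.base_topic] != grouping[c.intruder_topic]]
        intra = [c for c in cases if grouping[c.base_topic] == grouping[c.intruder_topic]]
        report["intergroup_accuracy"] = accuracy(inter)
        report["intragroup_accuracy"] = accuracy(intra)
        report["n_intergroup"] = len(inter)
        report["n_intragroup"] = len(intra)
    return report


def topic_distance_matrix(
    topic_word_counts: np.ndarray | None = None,
    beta: float = 0.01,
    intrusion_cases: Sequence[IntrusionCase] | None = None,
    intrusion_responses: Mapping[str, int] | None = None,
    topics: Sequence[int] | None = None,
) -> np.ndarray:
    """Symmetric topic-topic distance matrix from one of two backends.

    Automated backend: Jensen-Shannon divergence (nats; maximum ln 2) between
    the β-smoothed topic-word distributions. Intrusion backend: the mean
    intruder-detection accuracy per unordered pair — confusable topics give
    low accuracy and hence small distance; pairs with no responses are
    imputed at the maximum distance 1 with a warning.
    """
    if topic_word_counts is not None:
        phi = np.asarray(topic_word_counts, dtype=np.float64) + beta
        phi /= phi.sum(axis=1, keepdims=True)
        t_count = phi.shape[0]
        dist = np.zeros((t_count, t_count))
        for a in range(t_count):
            for b in range(a + 1, t_count):
                jsd = jensenshannon(phi[a], phi[b]) ** 2  # divergence, nats
                dist[a, b] = dist[b, a] = jsd
        return dist

    if intrusion_cases is None or intrusion_responses is None:
        raise ValueError("provide either topic_word_counts or intrusion cases+responses")
    if topics is None:
        topics = sorted(
            {c.base_topic for c in intrusion_cases}
            | {c.intruder_topic for c in intrusion_cases}
        )
    index = {t: i for i, t in enumerate(topics)}
    t_count = len(topics)
    hits = np.zeros((t_count, t_count))
    trials = np.zeros((t_count, t_count))
    for c in intrusion_cases:
        if c.case_id not in intrusion_responses:
            continue
        i, j = index[c.base_topic], index[c.intruder_topic]
        trials[i, j] += 1
        trials[j, i] += 1
        if intrusion_responses[c.case_id] == c.intruder_position:
            hits[i, j] += 1
            hits[j, i] += 1
    dist = np.ones((t_count, t_count))
    answered = trials > 0
    dist[answered] = hits[answered] / trials[answered]
    np.fill_diagonal(dist, 0.0)
    if not answered[np.triu_indices(t_count, 1)].all():
        warnings.warn("pairs without responses imputed at maximum distance 1", stacklevel=2)
    return dist


def classical_mds(distances: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling of a distance matrix:
    double-center the squared distances and embed on the top eigenvectors.
    Negative eigenvalues (non-Euclidean input) are truncated to zero."""
    d = np.asarray(distances, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1][:n_components]
    lam = np.clip(eigvals[order], 0.0, None)
    return eigvecs[:, order] * np.sqrt(lam)[None, :]


def build_hierarchy(
    distances: np.ndarray,
    n_components: int = 2,
    method: str = "average",
) -> np.ndarray:
    """Topic hierarchy: classical MDS embedding followed by agglomerative
    merging of the closest items. Returns the SciPy linkage matrix (merge
    heights are non-decreasing for average linkage)."""
    d = np.asarray(distances, dtype=np.float64)
    if d.shape[0] < 2:
        raise ValueError("need at least 2 topics")
    coords = classical_mds(d, n_components=n_components)
    diffs = coords[:, None, :] - coords[None, :, :]
    embedded = np.sqrt((diffs ** 2).sum(axis=-1))
    return linkage(squareform(embedded, checks=False), method=method)


def hierarchy_to_newick(z: np.ndarray, labels: Sequence[int | str]) -> str:
    """Render a linkage matrix as a Newick string; leaf names are topic ids,
    branch lengths are differences of merge heights."""
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(z)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


@dataclass
class CommunityProfile:
    community_id: int
    topic_counts: dict[int, int]
    theme_proportions: dict[str, float]
    user_count: int
    mean_posts_per_user: float


def community_profiles(
    table: ContingencyTable,
    theme_map: ThemeMap,
    user_counts: Mapping[int, int],
    unmapped: str | None = None,
) -> list[CommunityProfile]:
    """Per-community topic histogram, theme proportions and posting rate.

    ``user_counts`` maps community id → member count. Topics missing from
    the theme map raise unless an ``unmapped`` catch-all theme name (e.g.
    "other") is given. Theme proportions are over the community's posts and
    sum to 1.
    """
    profiles = []
    for i, comm in enumerate(table.community_ids):
        row = table.counts[i]
        topic_counts = {
            t: int(row[j]) for j, t in enumerate(table.topic_ids) if row[j] > 0
        }
        theme_totals: dict[str, int] = {}
        for t, cnt in topic_counts.items():
            if t in theme_map.topic_to_group:
                theme = theme_map.theme(t)
            elif unmapped is not None:
                theme = unmapped
            else:
                raise ValueError(f"topic {t} not covered by the theme map")
            theme_totals[theme] = theme_totals.get(theme, 0) + cnt
        total = sum(theme_totals.values())
        proportions = (
            {th: cnt / total for th, cnt in theme_totals.items()} if total else {}
        )
        n_users = user_counts[comm]
        profiles.append(
            CommunityProfile(
                community_id=comm,
                topic_counts=topic_counts,
                theme_proportions=proportions,
                user_count=n_users,
                mean_posts_per_user=int(row.sum()) / n_users if n_users else 0.0,
            )
        )
    return profiles


def majority_theme(profile: CommunityProfile) -> str:
    """Plurality theme of a community's posts; exact ties resolve in the
    fixed order evidence/advocacy > harms/conspiracies > experiential >
    lexicographic, and are flagged with a warning."""
    if not profile.theme_proportions:
        raise ValueError(f"community {profile.community_id} has no themed posts")
    best = max(profile.theme_proportions.values())
    tied = sorted(
        th for th, p in profile.theme_proportions.items() if p == best
    )
    if len(tied) > 1:
        warnings.warn(
            f"community {profile.community_id}: majority-theme tie {tied}",
            stacklevel=2,
        )
        order = {th: i for i, th in enumerate(THEME_TIE_ORDER)}
        tied.sort(key=lambda th: (order.get(th, len(order)), th))
    return tied[0]


def percentages_from_counts(counts: Mapping[str, int]) -> dict[str, float]:
    """Category percentages (two decimals) from raw counts."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty counts")
    return {k: round(100.0 * v / total, 2) for k, v in counts.items()}


@dataclass
class ExposureReport:
    focal_theme: str
    n_users: int
    counts: dict[str, int]             # majority theme (or "not connected") -> users
    percentages: dict[str, float]


def exposure_analysis(
    assignment: Mapping[str, int],
    authors: Mapping[str, str],
    partition: Partition | Mapping[str, int],
    theme_map: ThemeMap,
    table: ContingencyTable,
    user_counts: Mapping[int, int],
    focal_theme: str = "experiential",
    non_core_users: set[str] | None = None,
) -> ExposureReport:
    """Exposure of focal-theme posters to their community's dominant theme.

    Users with at least one post labeled with a ``focal_theme`` topic are
    tabulated by the majority theme of their community; users outside the
    community partition fall into the "not connected" category. When
    ``non_core_users`` is given, a focal user absent from both it and the
    partition raises a consistency error.
    """
    if focal_theme not in theme_map.group_to_theme.values():
        raise ValueError(f"theme {focal_theme!r} not defined in the theme map")
    membership = partition.membership if isinstance(partition, Partition) else partition
    profiles = community_profiles(table, theme_map, user_counts, unmapped="other")
    majority = {p.community_id: majority_theme(p) for p in profiles if p.theme_proportions}

    focal_users: set[str] = set()
    for pid, t in assignment.items():
        if t in theme_map.topic_to_group and theme_map.theme(t) == focal_theme:
            focal_users.add(authors[pid])

    counts: dict[str, int] = {}
    for user in sorted(focal_users):
        if user in membership:
            category = majority[membership[user]]
        else:
            if non_core_users is not None and user not in non_core_users:
                raise ValueError(f"user {user!r} in neither partition nor non-core list")
            category = "not connected"
        counts[category] = counts.get(category, 0) + 1
    return ExposureReport(
        focal_theme=focal_theme,
        n_users=len(focal_users),
        counts=counts,
        percentages=percentages_from_counts(counts) if counts else {},
    )
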