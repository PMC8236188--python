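import numpy as np
import pandas as pd
import pytest

from maplink.calls import (
    Call,
    CallMatrix,
    MAL_ROLES,
    PanelKind,
    ROLE_F2,
    ROLE_PARENT_ALT,
    ROLE_PARENT_REF,
)

A, H, B, M = int(Call.REF_HOM), int(Call.HET), int(Call.ALT_HOM), int(Call.MISSING)


def make_f2_panel(site_defs, n_lines, parent_calls=None, depth=10):
    """Build a small F2 CallMatrix from per-site F2 call/depth specs.

    site_defs: list of (unigene, position, f2_calls, f2_depths-or-None).
    parent_calls: optional list of (ref_call, alt_call) per site.
    """
    samples = ["DHA", "DHC"] + [f"L{i + 1:02d}" for i in range(n_lines)]
    roles = {"DHA": ROLE_PARENT_REF, "DHC": ROLE_PARENT_ALT}
    roles.update({s: ROLE_F2 for s in samples[2:]})
    calls, depths, rows = [], [], []
    for k, (u, pos, f2_calls, f2_depths) in enumerate(site_defs):
        pc = parent_calls[k] if parent_calls else (A, B)
        f2_depths = f2_depths if f2_depths is not None else [depth] * n_lines
        calls.append([pc[0], pc[1]] + list(f2_calls))
        depths.append([50, 50] + list(f2_depths))
        rows.append({"unigene": u, "position": pos})
    return CallMatrix(samples, roles, pd.DataFrame(rows),
                      np.array(calls, dtype=np.int8), np.array(depths, dtype=np.int32),
                      PanelKind.F2)


def make_mal_panel(site_defs, parent_calls=None, depth=10):
    """Build a small MAL CallMatrix.

    site_defs: list of (unigene, position, mal_calls(8), mal_depths-or-None).
    """
    samples = ["Fistulosum", "DHA"] + [f"MAL{c}" for c in range(1, 9)]
    roles = {"Fistulosum": ROLE_PARENT_ALT, "DHA": ROLE_PARENT_REF}
    roles.update({f"MAL{c}": MAL_ROLES[c - 1] for c in range(1, 9)})
    calls, depths, rows = [], [], []
    for k, (u, pos, mal_calls, mal_depths) in enumerate(site_defs):
        pc = parent_calls[k] if parent_calls else (B, A)  # (bunching onion, DHA)
        mal_depths = mal_depths if mal_depths is not None else [depth] * 8
        calls.append([pc[0], pc[1]] + list(mal_calls))
        depths.append([50, 50] + list(mal_depths))
        rows.append({"unigene": u, "position": pos})
    return CallMatrix(samples, roles, pd.DataFrame(rows),
                      np.array(calls, dtype=np.int8), np.array(depths, dtype=np.int32),
                      PanelKind.MAL)


@pytest.fixture
def mal_builder():
    return make_mal_panel


@pytest.fixture
def f2_builder():
    return make_f2_panel
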