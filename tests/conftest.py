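import math

import numpy as np
import pandas as pd
import pytest

from combitax.model import CONDITIONS, EBPrior, ModeratedFit


def make_fit(means, s2_tilde, df_tilde=8.0, n=3, feature_ids=None):
    """Construct a ModeratedFit directly from condition means and moderated
    variances, bypassing estimation — for tests that need exact inputs.

    ``means`` is a sequence of (C, A, B, AB) tuples, one per feature.
    """
    means = np.atleast_2d(np.asarray(means, dtype=float))
    k = means.shape[0]
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(k)]
    s2 = np.broadcast_to(np.asarray(s2_tilde, dtype=float), (k,)).copy()
    return ModeratedFit(
        means=pd.DataFrame(means, index=feature_ids, columns=list(CONDITIONS)),
        s2_tilde=pd.Series(s2, index=feature_ids),
        df_tilde=float(df_tilde),
        replicate_counts={c: n for c in CONDITIONS},
        degenerate=pd.Series(False, index=feature_ids),
        d_g=8,
        prior=EBPrior(d0=0.0, s0_2=1.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)
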