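"""Published reference aggregates from a real coral-mound survey.

The survey of the real mound (Porcupine Seabight, NE Atlantic) reported,
for each classifier, the per-facies total mapped area, object count and
area inside the mound boundary.  Those printed aggregates are the inputs of
the zonation worked examples: feeding them through the zonation arithmetic
must reproduce the published percentage-of-total-area and mean-object-area
cells.

Note the published sponge row for the DNN map prints a mound area (56.62 m2)
larger than the class total (46.22 m2), which is geometrically impossible;
the zonation routine warns on such rows instead of hiding them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_zonation"]


def load_reference_zonation(method: str | None = None) -> pd.DataFrame:
    """Per-class reference aggregates, optionally for one classifier.

    Returns a frame indexed by class code with columns ``total_area``,
    ``n_objects`` and ``mound_area`` (and ``method`` when not filtered).
    """
    with resources.files("mobia.data").joinpath(
        "reference_zonation.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    if method is not None:
        df = df[df["method"] == method].drop(columns="method")
        return df.set_index("class")
    return df.set_index(["method", "class"])
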