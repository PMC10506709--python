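"""hotspot1d: protein-protein interaction hot-spot residue prediction.

Per-residue feature matrices (one-hot or precomputed embeddings) are cut
into zero-padded sliding windows centered on annotated interface residues;
class imbalance is handled by interval subsampling of negatives plus SMOTE
synthesis (or class weighting), and a small 1-D convolutional network
classifies each window as hotspot (ddG > 2 kcal/mol) or not.
"""

__version__ = "0.1.0"

from .datamodel import (  # noqa: F401
    HOTSPOT,
    NON_HOTSPOT,
    HotspotDataset,
    ProteinRecord,
    ResidueAnnotation,
    dataset_summary,
    label_from_ddg,
)
from .embedders import concat_embed, load_precomputed, one_hot_embed  # noqa: F401
from .windowing import WindowConfig, WindowDataset, build_window_dataset, extract_window  # noqa: F401
from .assembly import (  # noqa: F401
    IntervalSamplerSpec,
    SmoteSpec,
    SplitSpec,
    assemble_training_set,
    compute_class_weights,
    interval_subsample,
    smote_generate,
    split_dataset,
)
from .model import CNN1DConfig, build_model, predict, resolve_depth, train  # noqa: F401
from .evaluation import ConfusionMatrix, MetricReport, confusion, metrics, roc_auc  # noqa: F401
from .synthetic import FeatureCloudSpec, SyntheticProteinSpec, generate_feature_cloud, generate_proteins  # noqa: F401
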