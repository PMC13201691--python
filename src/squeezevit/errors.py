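"""Exception hierarchy shared across the package."""


class SqueezeViTError(Exception):
    """Base class for package errors."""


class ConfigurationError(SqueezeViTError):
    """An invalid block, network or run configuration."""


class ShapeError(SqueezeViTError):
    """A tensor whose shape contradicts its consumer's contract."""


class GridError(ConfigurationError):
    """A patch grid that cannot tile the given feature map."""


class ManifestError(SqueezeViTError):
    """A label manifest that violates the CSV dialect or vocabulary."""


class UndefinedMetricError(SqueezeViTError):
    """A metric (e.g. AUROC) requested on degenerate labels."""
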