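"""Exception hierarchy shared across the pipeline stages."""


class TestisQuantError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TestisQuantError):
    """A config file, channel map or parameter set is inconsistent."""


class ChannelRoleError(ConfigurationError):
    """A channel role required downstream cannot be resolved to a channel."""


class SceneInfeasibleError(TestisQuantError):
    """Rejection sampling could not place the requested cells."""


class DegenerateImageError(TestisQuantError):
    """An image is constant where a histogram-based step needs contrast."""


class HubNotFoundError(TestisQuantError):
    """No connected component in the hub channel exceeds the minimum volume."""


class UndefinedCorrelationError(TestisQuantError):
    """Pearson r is undefined because a channel is constant within the mask."""
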