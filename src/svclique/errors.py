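"""Exception hierarchy with CLI exit codes.

0 = success, 2 = configuration error, 3 = input parse error,
4 = internal consistency violation.
"""


class SVCliqueError(Exception):
    exit_code = 1


class ConfigError(SVCliqueError):
    exit_code = 2


class InputParseError(SVCliqueError):
    exit_code = 3


class ConsistencyError(SVCliqueError):
    exit_code = 4
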