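import numpy as np
import pytest

import cavnet as cn


@pytest.fixture(scope="session")
def worked_example():
    """Five clusters, five sequences: {1,2,5}, {1,2,5}, {1,2}, {3,4}, {3,4}.

    Clusters 1 and 2 always fire together; cluster 5 joins them in 2 of 3
    sequences; clusters 3 and 4 have identical histories disjoint from the
    rest.
    """
    X = np.array(
        [
            [1, 1, 1, 0, 0],
            [1, 1, 1, 0, 0],
            [0, 0, 0, 1, 1],
            [0, 0, 0, 1, 1],
            [1, 1, 0, 0, 0],
        ],
        dtype=np.uint8,
    )
    return cn.CoactivationMatrix(X, [1, 2, 3, 4, 5])


@pytest.fixture(scope="session")
def small_cavity():
    """A default 36-cluster, 3-community cavity simulated for 30 minutes."""
    network = cn.generate_network(36, 3, seed=11)
    onsets, events = cn.simulate_activity(network, 1800.0, seed=12)
    trains = [cn.OnsetTrain(i, t) for i, t in enumerate(onsets)]
    sequences = cn.detect_sequences(trains)
    return {
        "network": network,
        "onsets": onsets,
        "events": events,
        "trains": trains,
        "sequences": sequences,
        "duration": 1800.0,
    }
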