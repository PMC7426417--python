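{
 "and-gate_serum1-dox/ground_truth.csv": "f8dedc6cf9d45616c53f79ceae506d4f01fa3237557af813cacce0ca2b7fa743",
 "and-gate_serum1-dox/ground_truth.csv.json": "a668e13922f670a2e6d95a21400947762da4585827cc16646a3f889ec13beb1f",
 "and-gate_serum1-dox/movie.tif": "a938bcc74526cfcaf75d5eba5de7c6b48ef83478a79f4dbbd661f6d559ad2efb",
 "and-gate_serum1-dox/movie.tif.json": "d28d9cf1168e12135bec5f41d01b6180acb2d9f8fdfd5c83e342d58f8e8016cd",
 "and-gate_serum1-dox/trajectory.csv": "fe75544532b9db4bfe162da6ee9502b2f76e496e57bfc1628673d141327f99d3",
 "and-gate_serum1-dox/trajectory.csv.json": "a668e13922f670a2e6d95a21400947762da4585827cc16646a3f889ec13beb1f",
 "btg2-btg2_serum10/ground_truth.csv": "6da72a17b0eb4e99b5d09f1b42911939ee8e63f1452bc4b185470b365208574f",
 "btg2-btg2_serum10/ground_truth.csv.json": "87154e17456c30c4acee923a89edc1e96df637df2119a9e1d881707a00c18797",
 "btg2-btg2_serum10/movie.tif": "00802493adabceaf0de7888546ca2f8729485e5de217143c4d6ef44be4b78d78",
 "btg2-btg2_serum10/movie.tif.json": "0f99e99f30e9c6c9d1c7c47a9a4fd5260aa3213e559fcca658950e01f4324571",
 "btg2-btg2_serum10/trajectory.csv": "68349cbff6f41a8d8ed1e076edf603810af9189098a17d66a25d1b9499ddd763",
 "btg2-btg2_serum10/trajectory.csv.json": "87154e17456c30c4acee923a89edc1e96df637df2119a9e1d881707a00c18797",
 "btg2-fos_serum10/ground_truth.csv": "4491c9c9d80a1cf868e1f82273ea70a555a58da375cd91861490f09284601821",
 "btg2-fos_serum10/ground_truth.csv.json": "bf671324eb107d687c0e2d1a84610d833ac83b27ef7f730004fba327e527bfbd",
 "btg2-fos_serum10/movie.tif": "819846d57361af6102670764b28ff5ebb874c9806771a1c16cda33eff6464f34",
 "btg2-fos_serum10/movie.tif.json": "c22fa7aeaabb41ab9b8fc93e22ecfa8a15ad1a4f8d80ae55c956f7cd984f233e",
 "btg2-fos_serum10/trajectory.csv": "197681e6b0094070694c6d5a7a1d287973ee2f1486cf94bc594f7436c35517ff",
 "btg2-fos_serum10/trajectory.csv.json": "bf671324eb107d687c0e2d1a84610d833ac83b27ef7f730004fba327e527bfbd",
 "fos-btg2_serum10/ground_truth.csv": "6da72a17b0eb4e99b5d09f1b42911939ee8e63f1452bc4b185470b365208574f",
 "fos-btg2_serum10/ground_truth.csv.json": "bdd50280744147441a8cea6a22b3290f21c5133e89aba91098eb4b4cd76f6867",
 "fos-btg2_serum10/movie.tif": "bd3038a98baebee082a22bb7ad3047bfa546a7b8d116de367df64e10867b78c4",
 "fos-btg2_serum10/movie.tif.json": "43d71ddf4c39eb834af195db86d19474a16c3bdcb1c8f9ca9490fe3301da172a",
 "fos-btg2_serum10/trajectory.csv": "68349cbff6f41a8d8ed1e076edf603810af9189098a17d66a25d1b9499ddd763",
 "fos-btg2_serum10/trajectory.csv.json": "bdd50280744147441a8cea6a22b3290f21c5133e89aba91098eb4b4cd76f6867",
 "fos-fos_serum1-dox/ground_truth.csv": "f67b4b13007f8e985aa0f2542bb5c405ceaa16925da343b033aaddbe22064f1f",
 "fos-fos_serum1-dox/ground_truth.csv.json": "85925516522b33c819619b1ec325793f55e2b8c7046dfbf03da3780b2da8dff3",
 "fos-fos_serum1-dox/movie.tif": "1e2836b75a933b6486025d6a3bd7d730eeea1d7aa33de82a496492a8aa54985a",
 "fos-fos_serum1-dox/movie.tif.json": "a607e4f02b879b2e88f3c0fdf32ed3bb6ebecab5e2e3c812fc457ca10f403385",
 "fos-fos_serum1-dox/trajectory.csv": "09245ca33dae8c64bc9cdf0724ee3ddff5161901dfdb9ca5caabcae8865b4eab",
 "fos-fos_serum1-dox/trajectory.csv.json": "85925516522b33c819619b1ec325793f55e2b8c7046dfbf03da3780b2da8dff3",
 "fos-fra1deg-fos_sustained/ground_truth.csv": "6bba27b3400dd10d8c751ae090e2b06915f9c4ef25688cf3c060e06384153183",
 "fos-fra1deg-fos_sustained/ground_truth.csv.json": "eb2c0071e1964ae818efca55b04793eaef1c953812730a59a1347bf3c631523b",
 "fos-fra1deg-fos_sustained/movie.tif": "9d62bc4ecfdc1d72bf7c9422f151822012971174e482cdb92b31fbd8e0492434",
 "fos-fra1deg-fos_sustained/movie.tif.json": "ee3c2e96647a831e4e4cf3647b0f9ca8d72d825ed59becfce38dc09026e9e75d",
 "fos-fra1deg-fos_sustained/trajectory.csv": "c347870b94c146344d0b67cc14f3ba8ddd8926dfd97d74e495d08eebad522896",
 "fos-fra1deg-fos_sustained/trajectory.csv.json": "eb2c0071e1964ae818efca55b04793eaef1c953812730a59a1347bf3c631523b",
 "fos-fra1deg-fos_transient20/ground_truth.csv": "a5e1b449641d3c3e814da5eec4ee7b95bb4e144f5c2e6670789fc31eb93cbbdf",
 "fos-fra1deg-fos_transient20/ground_truth.csv.json": "eb2c0071e1964ae818efca55b04793eaef1c953812730a59a1347bf3c631523b",
 "fos-fra1deg-fos_transient20/movie.tif": "7e5376d81c25986f67363c7e009319cb0e9780cdacc70d111863f30e6abe789b",
 "fos-fra1deg-fos_transient20/movie.tif.json": "0bc489618c8c19d37571a332de1e84bbf36326bac0ff672a8040166adb00375f",
 "fos-fra1deg-fos_transient20/trajectory.csv": "51838a9a3e289302bab7320013905b20adb9c4b2ee104bcb080a31c660cf5a55",
 "fos-fra1deg-fos_transient20/trajectory.csv.json": "eb2c0071e1964ae818efca55b04793eaef1c953812730a59a1347bf3c631523b",
 "fos-tubulin_sustained/ground_truth.csv": "584377179df87272edbfccf36b240b93aa20ae6e17837f1ef2ed41eab1281b97",
 "fos-tubulin_sustained/ground_truth.csv.json": "44ac094245188a9024f0e27b124bb3c47a5a45c066754c4c8eb06171d4a0df0a",
 "fos-tubulin_sustained/movie.tif": "a0c813bc32ad3355e73aa5990741c6bcd2012c8ab3e14230ad0fe1c53702c8b3",
 "fos-tubulin_sustained/movie.tif.json": "c36dc4a0a3c3a99cf61f3e2b70306be8ce4694c255b68abdb5994efbf9cf2216",
 "fos-tubulin_sustained/trajectory.csv": "311daf216c035a2c84cebad7de6a07c3ddedde0d729975651f4ae0b55bf74ec8",
 "fos-tubulin_sustained/trajectory.csv.json": "44ac094245188a9024f0e27b124bb3c47a5a45c066754c4c8eb06171d4a0df0a",
 "fos-tubulin_transient20/ground_truth.csv": "5af1fd2791d3f6ef573087cac97ee176a34d4627fe286eb22eb044cdddec27c3",
 "fos-tubulin_transient20/ground_truth.csv.json": "44ac094245188a9024f0e27b124bb3c47a5a45c066754c4c8eb06171d4a0df0a",
 "fos-tubulin_transient20/movie.tif": "4119feb175ccf5a181729d92752361ed6f14c3ad553f5ac2d2b06657c14df7b5",
 "fos-tubulin_transient20/movie.tif.json": "1b56733379f255ed1f50131219bc5766905236fb21f2ceafd7e1d60cd8faae6d",
 "fos-tubulin_transient20/trajectory.csv": "3602d2fe9a211bd3fef1f5eded826dee975863e1c6124ca4c786c34dff231034",
 "fos-tubulin_transient20/trajectory.csv.json": "44ac094245188a9024f0e27b124bb3c47a5a45c066754c4c8eb06171d4a0df0a"
}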