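wavenumber,selected_by,assignment,reference
1116.4,t+w,"CH2,6 in-plane bend and C1-Ca-Ha bend",ref30
1201.5,w,"Amide III (proteins)",ref31
1201.5,w,"Amide III: C-N stretching and N-H bending",ref32;ref33
1221.1,w,"Amide III (beta-sheet)",ref34
1221.1,w,"Amide III (proteins)",ref31;ref35
1234.2,t+w,"A concerted ring mode",ref36
1237.9,w,"Amide III & CH2 wagging: glycine backbone and proline side chains",ref37
1267.6,t+w,"C-H (lipid in healthy tissue)",ref33
1267.6,t+w,"Amide III (collagen assignment)",ref33
1272.3,w,"CHa' rocking",ref30
1290.7,w,"Cytosine",ref38
1420.5,t,"CH2 (lipid and protein)",ref35;ref39
1420.5,t,"DNA/RNA",ref31
1420.5,t,"Deoxyribose (B, Z-marker)",ref38
1488.2,t,"Guanine (N7)",ref38
1488.2,t,"Collagen",ref40
1578.9,t,"Guanine (N3)",ref38
1578.9,t,"Guanine, adenine",ref31
1610.4,t+w,"Cytosine (NH2)",ref38
1614.8,w,"Tyrosine",ref41
1634.0,w,"Amide I",ref37
1637.5,t,"Amide I",ref42;ref43
1650.5,t+w,"Amide I",ref33;ref44
1654.9,t,"Amide I",ref34;ref37;ref45;ref46
1654.9,t,"C=C stretching",ref46
1654.9,t,"Collagen",ref47
1660.9,t+w,"Amide I",ref31;ref48;ref49
1660.9,t+w,"C=C (lipids, fatty acids)",ref31;ref50;ref51
1660.9,t+w,"Ceramide backbone",ref51
1664.4,t+w,"Amide I",ref41
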